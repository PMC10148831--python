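"""Reading and writing minute-epoch actigraphy series and clinical tables.

The interchange formats are deliberately plain CSV dialects:

* **Actigraphy CSV** — two columns, ``timestamp`` (ISO-8601, minute
  precision, timezone-naive local clock time) and ``counts`` (nonnegative
  integer activity counts per minute).  Rows may be absent for some
  minutes; on read the series is re-gridded onto a contiguous one-minute
  grid and absent minutes become explicit missing values (NaN), which are
  distinct from recorded zero counts.
* **Clinical CSV** — one row per participant with columns
  ``participant_id, treatment, sex, age, hdrs_week0, hdrs_week1,
  hdrs_week8`` where ``treatment`` is ``SSRI``/``PBO`` and ``sex`` is
  ``F``/``M``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "ClinicalRecord",
    "SchemaError",
    "read_epoch_series",
    "write_epoch_series",
    "read_clinical_table",
    "write_clinical_table",
]

EPOCH = pd.Timedelta(minutes=1)

CLINICAL_COLUMNS = [
    "participant_id",
    "treatment",
    "sex",
    "age",
    "hdrs_week0",
    "hdrs_week1",
    "hdrs_week8",
]

HDRS_MAX = 52  # 17-item scale ceiling


class SchemaError(ValueError):
    """A file does not have the columns the dialect requires."""


@dataclass(frozen=True)
class EpochSeries:
    """One participant's minute-epoch activity counts on a contiguous grid.

    ``counts`` is a float array: nonnegative integers where observed and
    NaN where the minute has no recorded row.  Timestamps are implicit —
    epoch ``k`` is at ``start_time + k`` minutes.
    """

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-d sequence")
        observed = counts[~np.isnan(counts)]
        if observed.size and (observed < 0).any():
            raise ValueError("activity counts must be nonnegative")
        if self.start_time != self.start_time.floor("min"):
            raise ValueError("start_time must be at minute resolution")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="min")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of epochs with no recorded count."""
        return np.isnan(self.counts)

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    def hours_since_first_midnight(self) -> np.ndarray:
        """Elapsed hours of each epoch from the midnight opening the first day.

        This is the time axis used by the cosinor fit, so that phase is
        anchored to local clock time (days run midnight to midnight).
        """
        midnight = self.start_time.normalize()
        offset = (self.start_time - midnight) / pd.Timedelta(hours=1)
        return offset + np.arange(len(self)) / 60.0


@dataclass(frozen=True)
class ClinicalRecord:
    """Treatment arm, demographics and the three HDRS assessments."""

    participant_id: str
    treatment: str  # "SSRI" or "PBO"
    sex: str  # "F" or "M"
    age: float
    hdrs_week0: int
    hdrs_week1: int
    hdrs_week8: int

    def __post_init__(self) -> None:
        if self.treatment not in ("SSRI", "PBO"):
            raise ValueError(f"treatment must be SSRI or PBO, got {self.treatment!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if not (0 < self.age < 120):
            raise ValueError(f"age out of range: {self.age}")
        for name in ("hdrs_week0", "hdrs_week1", "hdrs_week8"):
            v = getattr(self, name)
            if not (0 <= v <= HDRS_MAX):
                raise ValueError(f"{name} out of range [0, {HDRS_MAX}]: {v}")


def read_epoch_series(path: str | os.PathLike, participant_id: str | None = None) -> EpochSeries:
    """Read an actigraphy CSV and re-grid it onto contiguous minutes.

    Absent minutes between the first and last timestamp become NaN.
    Raises on malformed timestamps, negative counts and duplicate
    timestamps, naming the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"counts": "object"})
    missing_cols = {"timestamp", "counts"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"actigraphy CSV missing column(s): {sorted(missing_cols)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 1
        raise ValueError(f"{path}: malformed timestamp at row {row}")
    counts = pd.to_numeric(df["counts"], errors="coerce")
    if counts.isna().any():
        row = int(np.flatnonzero(counts.isna().to_numpy())[0]) + 1
        raise ValueError(f"{path}: non-numeric count at row {row}")
    if (counts < 0).any():
        row = int(np.flatnonzero((counts < 0).to_numpy())[0]) + 1
        raise ValueError(f"{path}: negative count at row {row}")
    if ts.duplicated().any():
        row = int(np.flatnonzero(ts.duplicated().to_numpy())[0]) + 1
        raise ValueError(f"{path}: duplicate timestamp at row {row}")
    if not ts.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps must be sorted ascending")
    floored = ts.dt.floor("min")
    if (floored != ts).any():
        row = int(np.flatnonzero((floored != ts).to_numpy())[0]) + 1
        raise ValueError(f"{path}: timestamp not at minute resolution at row {row}")

    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="min")
    regridded = pd.Series(counts.to_numpy(dtype=float), index=ts).reindex(grid)
    if participant_id is None:
        participant_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return EpochSeries(
        participant_id=participant_id,
        start_time=grid[0],
        counts=regridded.to_numpy(),
    )


def write_epoch_series(series: EpochSeries, path: str | os.PathLike) -> None:
    """Write an actigraphy CSV; missing epochs are omitted (no row)."""
    obs = ~series.missing
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps[obs].strftime("%Y-%m-%dT%H:%M"),
            "counts": series.counts[obs].astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_clinical_table(path: str | os.PathLike) -> list[ClinicalRecord]:
    """Read the clinical CSV into validated records, one per participant."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"clinical CSV missing column(s): {sorted(missing_cols)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"{path}: duplicate participant_id {dup!r}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ClinicalRecord(
                    participant_id=str(row["participant_id"]),
                    treatment=str(row["treatment"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    hdrs_week0=int(row["hdrs_week0"]),
                    hdrs_week1=int(row["hdrs_week1"]),
                    hdrs_week8=int(row["hdrs_week8"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid record at row {i + 1}: {exc}") from exc
    return records


def write_clinical_table(records: list[ClinicalRecord], path: str | os.PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[CLINICAL_COLUMNS].to_csv(
        path, index=False
    )


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by participant_id."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("participant_id")
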