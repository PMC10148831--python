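"""Non-wear detection (Choi algorithm) and wear-time inclusion filters.

The device is assumed unworn during long runs of zero counts.  The Choi
rule marks a maximal run of zeros of at least ``window`` minutes
(default 90) as non-wear; short nonzero "artifact" bursts of at most
``artifact_max`` minutes (default 2) are absorbed into the surrounding
zero run when flanked by at least ``flank`` minutes (default 30) of
consecutive zeros on both sides.  Epochs with no recorded count are
treated like zeros for detection and always end up non-wear.

Downstream measures never see non-wear epochs as zeros: the wear mask is
applied on the original timestamp grid, so clock-time-aligned measures
(M10/L5 windows, hourly bins, cosinor phase) stay anchored to local time.

A valid day is a midnight-to-midnight calendar date with at least 900
worn minutes — enough to place a 600-minute most-active and a
300-minute least-active window without forcing overlap.  A participant
enters analysis with at least 4 valid days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSeries

__all__ = [
    "WearProfile",
    "detect_nonwear_choi",
    "apply_inclusion_filters",
    "masked_counts",
    "MIN_DAY_MINUTES",
    "MIN_VALID_DAYS",
]

MIN_DAY_MINUTES = 900
MIN_VALID_DAYS = 4


@dataclass(frozen=True)
class WearProfile:
    """Per-epoch wear classification plus valid-day bookkeeping."""

    participant_id: str
    wear_mask: np.ndarray  # bool, True = worn
    valid_days: tuple  # calendar dates with >= MIN_DAY_MINUTES worn minutes

    @property
    def worn_minutes_total(self) -> int:
        return int(self.wear_mask.sum())


def _zero_runs(is_zero: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans of maximal True runs."""
    padded = np.concatenate(([False], is_zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_nonwear_choi(
    series: EpochSeries,
    window: int = 90,
    artifact_max: int = 2,
    flank: int = 30,
) -> WearProfile:
    """Classify every epoch as wear or non-wear with the Choi rule.

    Zero runs separated by a nonzero gap of at most ``artifact_max``
    minutes are chained together when the runs adjacent to the gap are
    each at least ``flank`` minutes long; a chained span (artifact
    minutes included) of at least ``window`` minutes is non-wear.
    Missing epochs count as zeros here and are non-wear regardless.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if not (window >= flank >= artifact_max >= 1):
        raise ValueError("require window >= flank >= artifact_max >= 1")

    counts = series.counts
    is_zeroish = np.isnan(counts) | (counts == 0)
    runs = _zero_runs(is_zeroish)

    nonwear = np.zeros(len(series), dtype=bool)
    i = 0
    while i < len(runs):
        span_start = runs[i][0]
        j = i
        # chain runs across absorbable artifact gaps
        while j + 1 < len(runs):
            gap = runs[j + 1][0] - runs[j][1]
            left_len = runs[j][1] - runs[j][0]
            right_len = runs[j + 1][1] - runs[j + 1][0]
            if gap <= artifact_max and left_len >= flank and right_len >= flank:
                j += 1
            else:
                break
        span_stop = runs[j][1]
        if span_stop - span_start >= window:
            nonwear[span_start:span_stop] = True
        i = j + 1

    nonwear |= np.isnan(counts)
    wear = ~nonwear

    dates = series.timestamps.normalize()
    worn_per_day = pd.Series(wear, index=dates).groupby(level=0).sum()
    valid = tuple(d.date() for d, m in worn_per_day.items() if m >= MIN_DAY_MINUTES)
    return WearProfile(
        participant_id=series.participant_id, wear_mask=wear, valid_days=valid
    )


def apply_inclusion_filters(
    profile: WearProfile, min_valid_days: int = MIN_VALID_DAYS
) -> tuple[bool, tuple]:
    """Participant-level inclusion: at least ``min_valid_days`` valid days.

    Returns ``(included, valid_days)``; exclusion is a normal outcome,
    not an error.
    """
    return len(profile.valid_days) >= min_valid_days, profile.valid_days


def masked_counts(series: EpochSeries, profile: WearProfile) -> np.ndarray:
    """Counts with non-wear (and missing) epochs replaced by NaN.

    The grid and timestamps are unchanged, so index ``k`` still refers to
    ``start_time + k`` minutes.
    """
    if len(profile.wear_mask) != len(series):
        raise ValueError("wear mask length does not match series")
    out = series.counts.astype(float).copy()
    out[~profile.wear_mask] = np.nan
    return out


def qc_table(series: EpochSeries, profile: WearProfile) -> pd.DataFrame:
    """Per-day worn minutes and validity, for the QC report."""
    dates = series.timestamps.normalize()
    worn = pd.Series(profile.wear_mask, index=dates).groupby(level=0).sum()
    return pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "date": [d.date() for d in worn.index],
            "worn_minutes": worn.to_numpy(dtype=int),
            "valid_day": [d.date() in set(profile.valid_days) for d in worn.index],
        }
    )
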