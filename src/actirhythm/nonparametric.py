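"""Nonparametric rest-activity measures: M10, L5, RA, IV, IS.

These make no waveform assumption.  M10 and L5 are the mean activity
over the most active 10 and least active 5 consecutive hours of a day;
relative amplitude is their normalized contrast

    RA = (M10 - L5) / (M10 + L5),      RA in [0, 1] for nonnegative counts.

Intradaily variability and interdaily stability are computed on hourly
means.  With hourly points x_1..x_N (grand mean x_bar) and s samples per
day,

    IV = N * sum_{i=2..N} (x_i - x_{i-1})^2
         / [ (N-1) * sum_i (x_i - x_bar)^2 ]

    IS = N * sum_{h=1..s} (x_bar_h - x_bar)^2
         / [ s * sum_i (x_i - x_bar)^2 ]

where x_bar_h is the across-day mean for hour-of-day h.  IV is the mean
squared first difference over the variance: near 0 for a smooth diurnal
profile, near 2 for white noise, larger for strongly fragmented
(alternating) patterns.  IS is the fraction of variance explained by the
average 24-h profile, in [0, 1].

Missing hours (insufficient wear coverage) are handled by dropping
first-difference pairs that span a gap and by taking realized point,
pair, and hour-bin counts in the normalizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSeries
from .preprocess import WearProfile, masked_counts

__all__ = [
    "HourlySeries",
    "NonparametricSummary",
    "window_activity",
    "day_matrix",
    "compute_m10_l5_ra",
    "hourly_bin",
    "compute_iv",
    "compute_is",
    "nonparametric_summary",
]

MINUTES_PER_DAY = 1440
M10_WIDTH = 600  # minutes
L5_WIDTH = 300  # minutes
WINDOW_COVERAGE = 0.75  # fraction of window minutes that must be observed
HOURLY_MIN_MINUTES = 30  # observed minutes for an hourly mean to count


@dataclass(frozen=True)
class HourlySeries:
    """Hourly activity means on a contiguous clock-hour grid.

    ``values`` runs from the first midnight of the recording in 1-hour
    steps, NaN where the hour had under ``HOURLY_MIN_MINUTES`` observed
    minutes, so position ``i`` is hour-of-day ``i % 24``.
    """

    values: np.ndarray
    samples_per_day: int = 24

    @property
    def n_observed(self) -> int:
        return int((~np.isnan(self.values)).sum())

    @property
    def hour_of_day(self) -> np.ndarray:
        return np.arange(self.values.size) % self.samples_per_day


@dataclass(frozen=True)
class NonparametricSummary:
    m10: float
    l5: float
    ra: float
    iv: float
    is_: float
    m10_onset_hour: float
    l5_onset_hour: float
    n_valid_days: int


def window_activity(day: np.ndarray, width: int, mode: str):
    """Best window mean over `width` consecutive minutes of one day.

    ``day`` is a 1440-long minute array with NaN for unworn/missing
    minutes.  Scans every day-bounded window start, keeps windows with at
    least 75% observed coverage, and returns ``(mean, start_minute)`` for
    the maximal (mode="most") or minimal (mode="least") window mean,
    earliest start winning ties.  Returns ``(nan, nan)`` when no window
    has enough coverage.
    """
    if mode not in ("most", "least"):
        raise ValueError("mode must be 'most' or 'least'")
    day = np.asarray(day, dtype=float)
    if day.size != MINUTES_PER_DAY:
        raise ValueError(f"day must have {MINUTES_PER_DAY} minutes")
    observed = ~np.isnan(day)
    filled = np.where(observed, day, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(observed)))
    win_sum = csum[width:] - csum[:-width]
    win_cnt = ccnt[width:] - ccnt[:-width]
    ok = win_cnt >= WINDOW_COVERAGE * width
    if not ok.any():
        return float("nan"), float("nan")
    means = np.full(win_sum.size, np.nan)
    means[ok] = win_sum[ok] / win_cnt[ok]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        start = int(np.nanargmax(means) if mode == "most" else np.nanargmin(means))
    return float(means[start]), start


def day_matrix(values: np.ndarray, timestamps: pd.DatetimeIndex):
    """Reshape a minute series into (dates, n_days x 1440), NaN-padded.

    Rows run midnight to midnight; minutes outside the recording are NaN.
    """
    if len(values) != len(timestamps):
        raise ValueError("values and timestamps length mismatch")
    first = timestamps[0].normalize()
    offsets = ((timestamps - first) / pd.Timedelta(minutes=1)).astype(int)
    n_days = offsets[-1] // MINUTES_PER_DAY + 1
    mat = np.full(n_days * MINUTES_PER_DAY, np.nan)
    mat[offsets] = values
    dates = tuple((first + pd.Timedelta(days=int(d))).date() for d in range(n_days))
    return dates, mat.reshape(n_days, MINUTES_PER_DAY)


def compute_m10_l5_ra(series: EpochSeries, profile: WearProfile):
    """Per-day M10/L5 window means averaged over valid days, and their RA.

    RA is computed from the averaged M10 and L5.  Also returns the mean
    window-onset clock hours.  Days whose window search fails coverage
    contribute nothing to that measure's average.
    """
    values = masked_counts(series, profile)
    dates, mat = day_matrix(values, series.timestamps)
    valid = set(profile.valid_days)
    m10s, l5s, m10_starts, l5_starts = [], [], [], []
    for date, day in zip(dates, mat):
        if date not in valid:
            continue
        m10, s10 = window_activity(day, M10_WIDTH, "most")
        l5, s5 = window_activity(day, L5_WIDTH, "least")
        if not np.isnan(m10):
            m10s.append(m10)
            m10_starts.append(s10 / 60.0)
        if not np.isnan(l5):
            l5s.append(l5)
            l5_starts.append(s5 / 60.0)
    if not m10s or not l5s:
        raise ValueError("no valid day yields both M10 and L5 windows")
    m10 = float(np.mean(m10s))
    l5 = float(np.mean(l5s))
    ra = (m10 - l5) / (m10 + l5) if (m10 + l5) > 0 else float("nan")
    return m10, l5, ra, float(np.mean(m10_starts)), float(np.mean(l5_starts))


def hourly_bin(series: EpochSeries, profile: WearProfile) -> HourlySeries:
    """Mean observed activity per clock hour, NaN under 30 observed minutes."""
    values = masked_counts(series, profile)
    _, mat = day_matrix(values, series.timestamps)
    by_hour = mat.reshape(-1, 60)  # (n_days*24, 60)
    n_obs = (~np.isnan(by_hour)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(by_hour, axis=1)
    means[n_obs < HOURLY_MIN_MINUTES] = np.nan
    return HourlySeries(values=means)


def compute_iv(hourly: HourlySeries | np.ndarray) -> float:
    """Intradaily variability of an hourly series.

    Mean squared successive difference over the (population) variance of
    the observed points; successive-difference pairs that span a missing
    hour are dropped.
    """
    x = hourly.values if isinstance(hourly, HourlySeries) else np.asarray(hourly, float)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("IV needs at least 3 observed hourly points")
    pair = obs[1:] & obs[:-1]
    if not pair.any():
        warnings.warn("IV undefined: no adjacent hourly pairs", stacklevel=2)
        return float("nan")
    diffs = (x[1:] - x[:-1])[pair]
    var = float(((x[obs] - x[obs].mean()) ** 2).sum()) / n
    if var == 0.0:
        warnings.warn("IV undefined: zero variance", stacklevel=2)
        return float("nan")
    return float((diffs**2).mean() / var)


def compute_is(hourly: HourlySeries | np.ndarray, samples_per_day: int = 24) -> float:
    """Interdaily stability of an hourly series.

    Variance of the mean 24-hour profile over the total variance, with
    missing hours omitted from their hour-of-day means and realized
    counts in the normalizations.
    """
    if isinstance(hourly, HourlySeries):
        x, s = hourly.values, hourly.samples_per_day
    else:
        x, s = np.asarray(hourly, float), samples_per_day
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("IS needs at least 2 observed hourly points")
    hod = np.arange(x.size) % s
    if len(np.unique((np.arange(x.size) // s)[obs])) < 2:
        raise ValueError("IS needs observations from at least 2 days")
    grand = x[obs].mean()
    total = float(((x[obs] - grand) ** 2).sum())
    if total == 0.0:
        warnings.warn("IS undefined: zero variance", stacklevel=2)
        return float("nan")
    between = 0.0
    s_realized = 0
    for h in range(s):
        sel = obs & (hod == h)
        if sel.any():
            between += (x[sel].mean() - grand) ** 2
            s_realized += 1
    return float(n * between / (s_realized * total))


def nonparametric_summary(series: EpochSeries, profile: WearProfile) -> NonparametricSummary:
    """All five nonparametric measures for one included participant."""
    m10, l5, ra, m10_on, l5_on = compute_m10_l5_ra(series, profile)
    hourly = hourly_bin(series, profile)
    return NonparametricSummary(
        m10=m10,
        l5=l5,
        ra=ra,
        iv=compute_iv(hourly),
        is_=compute_is(hourly),
        m10_onset_hour=m10_on,
        l5_onset_hour=l5_on,
        n_valid_days=len(profile.valid_days),
    )
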