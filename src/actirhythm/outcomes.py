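"""Depression-change outcomes from HDRS scores.

HDRS totals are positively skewed, so change is measured on the log
scale: the week-k outcome is ln(week_k / week_0), negative values
meaning improvement.  A log-change d corresponds to a percent change of
(exp(d) - 1) * 100; the ratio is truncated to three decimals before
differencing so printed percentages agree with the ratio shown alongside
them.  Remission is a week-8 HDRS total of at most 7.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "OutcomeRecord",
    "delta_hdrs",
    "pct_change",
    "classify_remission",
    "outcome_record",
    "REMISSION_CUTOFF",
]

REMISSION_CUTOFF = 7
ZERO_SCORE_CLAMP = 0.5


@dataclass(frozen=True)
class OutcomeRecord:
    participant_id: str
    delta_hdrs1: float  # ln(week1 / week0)
    delta_hdrs8: float  # ln(week8 / week0)
    remitter: bool


def delta_hdrs(week_k: float, week_0: float) -> float:
    """Log-ratio change ln(week_k / week_0) of an HDRS total from baseline.

    A zero post-baseline score is clamped to 0.5 (with a warning) so a
    fully remitted participant keeps a finite, strongly negative change;
    a zero baseline has no meaningful ratio and is an error.
    """
    if week_0 <= 0:
        raise ValueError("baseline HDRS must be >= 1 for the log-ratio outcome")
    if week_k < 0:
        raise ValueError("HDRS scores are nonnegative")
    if week_k == 0:
        warnings.warn(
            f"HDRS score 0 clamped to {ZERO_SCORE_CLAMP} before log transform",
            stacklevel=2,
        )
        week_k = ZERO_SCORE_CLAMP
    return math.log(week_k / week_0)


def pct_change(delta: float) -> float:
    """Percent change in HDRS implied by a log-change.

    The ratio exp(delta) is truncated to 3 decimals before differencing,
    e.g. delta = -0.176 -> ratio 0.838 -> -16.2%.
    """
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    ratio = math.floor(math.exp(delta) * 1000.0) / 1000.0
    return (ratio - 1.0) * 100.0


def classify_remission(hdrs_week8: float) -> bool:
    """Remitter iff the week-8 HDRS total is <= 7."""
    if hdrs_week8 < 0:
        raise ValueError("HDRS scores are nonnegative")
    return hdrs_week8 <= REMISSION_CUTOFF


def outcome_record(
    participant_id: str, hdrs_week0: int, hdrs_week1: int, hdrs_week8: int
) -> OutcomeRecord:
    return OutcomeRecord(
        participant_id=participant_id,
        delta_hdrs1=delta_hdrs(hdrs_week1, hdrs_week0),
        delta_hdrs8=delta_hdrs(hdrs_week8, hdrs_week0),
        remitter=classify_remission(hdrs_week8),
    )
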