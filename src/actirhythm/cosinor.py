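"""Single-component cosinor rhythmometry on minute-epoch activity.

The model for one participant's activity at time ``t`` (hours) is

    Y(t) = M + A * cos(2*pi*t/tau + phi) + e(t)

with period ``tau`` fixed at 24 h.  Expanding the cosine turns this into
an ordinary least-squares problem in (M, beta, gamma) with regressors
x = cos(2*pi*t/tau) and z = sin(2*pi*t/tau), where beta = A*cos(phi) and
gamma = -A*sin(phi).  The fit pools every worn minute of the whole
recording into one regression; amplitude and acrophase are recovered
from (beta, gamma), and the circadian quotient CQ = A/M is the
scale-free index of rhythm robustness.

Acrophase is reported in radians on (-2*pi, 0]; the corresponding peak
clock time in hours is -phi*tau/(2*pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EpochSeries
from .preprocess import WearProfile, masked_counts

__all__ = [
    "CosinorEstimate",
    "build_cosinor_design",
    "fit_cosinor",
    "acrophase_to_clock",
]

TAU_HOURS = 24.0


@dataclass(frozen=True)
class CosinorEstimate:
    mesor: float  # counts/min
    amplitude: float  # counts/min, >= 0
    acrophase: float  # radians in (-2*pi, 0]; 0 when degenerate
    beta: float
    gamma: float
    cq: float  # amplitude / mesor; NaN when mesor <= 0
    r_squared: float
    residual_variance: float
    n_obs: int
    period: float = TAU_HOURS
    degenerate_phase: bool = False

    @property
    def peak_clock_hour(self) -> float:
        return acrophase_to_clock(self.acrophase, self.period)


def build_cosinor_design(times_hours: np.ndarray, tau: float = TAU_HOURS):
    """Cosine/sine regressor pair (x, z) for the linearized cosinor fit."""
    if tau <= 0:
        raise ValueError("period tau must be positive")
    t = np.asarray(times_hours, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    angle = 2.0 * np.pi * t / tau
    return np.cos(angle), np.sin(angle)


def _wrap_acrophase(phi: float) -> float:
    """Map an angle into the half-open interval (-2*pi, 0]."""
    phi = float(np.mod(phi, 2.0 * np.pi))  # [0, 2*pi)
    return phi - 2.0 * np.pi if phi > 0 else 0.0


def fit_cosinor(
    series: EpochSeries, wear: WearProfile, tau: float = TAU_HOURS
) -> CosinorEstimate:
    """Least-squares cosinor fit over all worn epochs of the recording.

    Non-wear and missing epochs are excluded from the regression rather
    than zero-filled (zeros would drag both MESOR and amplitude down).
    """
    y = masked_counts(series, wear)
    t = series.hours_since_first_midnight()
    obs = ~np.isnan(y)
    y, t = y[obs], t[obs]
    if y.size < 3:
        raise ValueError("cosinor fit needs at least 3 worn epochs")
    if t.max() - t.min() <= 0:
        raise ValueError("worn epochs span zero time")

    x, z = build_cosinor_design(t, tau)
    X = np.column_stack([np.ones_like(x), x, z])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient cosinor design (degenerate sampling times)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)

    amplitude = float(np.hypot(beta, gamma))
    # amplitude at numerical-noise scale leaves the phase meaningless
    degenerate = amplitude <= 1e-10 * max(1.0, abs(mesor))
    if degenerate:
        amplitude = amplitude if amplitude > 0 else 0.0
    # beta = A cos(phi), gamma = -A sin(phi)
    acrophase = 0.0 if degenerate else _wrap_acrophase(np.arctan2(-gamma, beta))

    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - sse / sst if sst > 0 else 0.0
    dof = max(y.size - 3, 1)

    if mesor > 0:
        cq = amplitude / mesor
    else:
        warnings.warn(
            f"{series.participant_id}: MESOR <= 0, circadian quotient undefined",
            stacklevel=2,
        )
        cq = float("nan")

    return CosinorEstimate(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        beta=beta,
        gamma=gamma,
        cq=cq,
        r_squared=r_squared,
        residual_variance=sse / dof,
        n_obs=int(y.size),
        period=tau,
        degenerate_phase=degenerate,
    )


def acrophase_to_clock(phi: float, tau: float = TAU_HOURS) -> float:
    """Peak clock time in hours, in [0, tau), from an acrophase in (-2*pi, 0]."""
    if not (-2.0 * np.pi < phi <= 0.0):
        raise ValueError("acrophase must lie in (-2*pi, 0]")
    return float(np.mod(-phi * tau / (2.0 * np.pi), tau))
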