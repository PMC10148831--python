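"""Synthetic cohorts of minute-epoch actigraphy and HDRS trajectories.

Each simulated participant has a ground-truth cosine rest-activity
rhythm: minute intensity

    lam(t) = max(0, M + A*cos(2*pi*t/24 + phi) + day offset + event perturbations)

with MESOR M lognormal (median 200 counts/min), circadian quotient
CQ = A/M truncated normal (mean 0.80, SD 0.18), and acrophase normal
(mean -4.1 rad, i.e. a mid-afternoon activity peak).  Observed counts
are overdispersed nonnegative integers (gamma-Poisson mixture) around
lam; setting ``dispersion = 0`` switches every stochastic signal layer
off and emits the truncated cosine itself, so the extraction pipeline
can be checked for exact parameter recovery.

Realism layers, each with its own knob:

* per-day additive offsets (day-to-day jitter) that depress interdaily
  stability;
* nap/arousal events (suppressed daytime or elevated nighttime activity
  for tens of minutes) that raise intradaily variability;
* non-wear bouts of at least 90 min written as zero runs, which the
  Choi detector should recover.

Clinical trajectories: baseline HDRS is drawn near the trial's case mix
(mean ~17.8, SD ~4.8); the week-1 score follows a log-linear model

    ln W1 = ln W0 + drift + beta_cq_week * CQ_std + beta_ssri_week * SSRI + eps

whose ``beta_cq_week`` coefficient (default 0.11) is the ground truth
the repeated-measures model should recover.  The week-8 score is a
two-component mixture (a strongly improving "remitting" component and a
modestly improving one) independent of week-1 circadian features by
default, so remission labels emerge from the simulated scores via the
HDRS <= 7 rule rather than being assigned.

All randomness descends from one seed through ``numpy`` SeedSequence
spawning: stream 0 drives cohort-level draws, stream i+1 participant
i's signal, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .io import ClinicalRecord, EpochSeries, write_clinical_table, write_epoch_series

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_participant",
    "simulate_cohort",
    "simulate_clinical_cohort",
]

MINUTES_PER_DAY = 1440
HDRS_CEILING = 52
START_DATE = "2020-01-06"  # a Monday; any fixed local date works


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults emulate the target trial's cohort."""

    n_participants: int = 40
    days: int = 7
    seed: int = 0
    # circadian signal
    mesor_median: float = 200.0  # counts/min, lognormal median
    mesor_sigma: float = 0.45  # lognormal shape
    cq_mean: float = 0.80
    cq_sd: float = 0.18
    cq_bounds: tuple[float, float] = (0.05, 1.2)
    acrophase_mean: float = -4.1  # rad
    acrophase_sd: float = 0.9
    dispersion: float = 3.0  # gamma-Poisson shape; 0 = deterministic signal
    hourly_env_sigma: float = 0.45  # lognormal sigma of the mean-1 hourly envelope
    nap_rate: float = 0.75  # events per day
    event_duration_mean: float = 45.0  # minutes
    arousal_strength: float = 0.25  # nighttime burst, as a fraction of amplitude
    day_jitter_sd: float = 20.0  # counts/min, per-day offset
    nonwear_bouts_per_week: float = 1.0
    nonwear_bout_min: float = 90.0  # minutes
    nonwear_bout_extra_mean: float = 60.0  # exponential tail beyond the minimum
    # demographics / clinical
    female_fraction: float = 0.70
    age_min: float = 18.0
    age_max: float = 64.0
    age_gamma_shape: float = 1.3
    age_gamma_scale: float = 10.0
    hdrs0_mean: float = 17.8
    hdrs0_sd: float = 4.8
    hdrs0_bounds: tuple[int, int] = (8, 35)
    # week-1 outcome model (log scale)
    week1_drift: float = -0.11
    beta_cq_week: float = 0.11
    beta_ssri_week: float = -0.14
    week1_resid_sd: float = 0.18
    # week-8 outcome mixture (log scale)
    week8_remit_frac: float = 0.40
    week8_drift_remit: float = -1.39
    week8_drift_nonremit: float = -0.32
    week8_sd_remit: float = 0.45
    week8_sd_nonremit: float = 0.30
    beta_cq_week8: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "mesor_sigma", "cq_sd", "acrophase_sd", "day_jitter_sd",
            "week1_resid_sd", "week8_sd_remit", "week8_sd_nonremit",
            "hdrs0_sd", "nap_rate", "nonwear_bouts_per_week", "dispersion",
            "hourly_env_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.cq_bounds
        if not (0 < lo < hi < 2):
            raise ValueError("cq truncation bounds must lie within (0, 2)")
        if not 1 <= self.days:
            raise ValueError("days must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    participant_id: str
    mesor: float
    amplitude: float
    acrophase: float
    cq: float
    cq_std: float
    nonwear_intervals: tuple  # (start_epoch, stop_epoch) half-open
    remitter: bool
    week8_component: str  # "remit" or "nonremit" mixture component


def _truncated_normal(rng, mean, sd, bounds, size):
    lo, hi = bounds
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_cohort_params(config: SimulationConfig, rng: np.random.Generator):
    """Participant-level ground-truth parameters, covariates and HDRS."""
    n = config.n_participants
    mesor = config.mesor_median * np.exp(rng.normal(0, config.mesor_sigma, n))
    cq = _truncated_normal(rng, config.cq_mean, config.cq_sd, config.cq_bounds, n)
    acrophase = rng.normal(config.acrophase_mean, config.acrophase_sd, n)
    cq_std = (cq - cq.mean()) / cq.std(ddof=1)

    ssri = np.zeros(n)
    ssri[rng.permutation(n)[: n // 2]] = 1.0
    female = rng.random(n) < config.female_fraction
    age = np.clip(
        config.age_min + rng.gamma(config.age_gamma_shape, config.age_gamma_scale, n),
        config.age_min,
        config.age_max,
    )

    hdrs0 = np.clip(
        np.rint(rng.normal(config.hdrs0_mean, config.hdrs0_sd, n)),
        *config.hdrs0_bounds,
    ).astype(int)
    ln_w1 = (
        np.log(hdrs0)
        + config.week1_drift
        + config.beta_cq_week * cq_std
        + config.beta_ssri_week * ssri
        + rng.normal(0, config.week1_resid_sd, n)
    )
    hdrs1 = np.clip(np.rint(np.exp(ln_w1)), 1, HDRS_CEILING).astype(int)

    remit_component = rng.random(n) < config.week8_remit_frac
    drift8 = np.where(
        remit_component, config.week8_drift_remit, config.week8_drift_nonremit
    )
    sd8 = np.where(remit_component, config.week8_sd_remit, config.week8_sd_nonremit)
    ln_w8 = (
        np.log(hdrs0) + drift8 + config.beta_cq_week8 * cq_std + rng.normal(0, 1, n) * sd8
    )
    hdrs8 = np.clip(np.rint(np.exp(ln_w8)), 1, HDRS_CEILING).astype(int)

    return {
        "mesor": mesor,
        "cq": cq,
        "cq_std": cq_std,
        "amplitude": cq * mesor,
        "acrophase": acrophase,
        "ssri": ssri,
        "female": female,
        "age": age,
        "hdrs0": hdrs0,
        "hdrs1": hdrs1,
        "hdrs8": hdrs8,
        "remit_component": remit_component,
    }


def simulate_participant(
    config: SimulationConfig,
    rng: np.random.Generator,
    mesor: float,
    amplitude: float,
    acrophase: float,
) -> tuple[EpochSeries, tuple]:
    """Minute-level count series for one participant's ground-truth rhythm.

    Returns the series and the injected non-wear intervals (half-open
    epoch spans).  With ``dispersion = 0`` all stochastic layers are off
    and counts equal the truncated cosine exactly (as floats).
    """
    n_min = config.days * MINUTES_PER_DAY
    t_hours = np.arange(n_min) / 60.0
    lam = mesor + amplitude * np.cos(2 * np.pi * t_hours / 24.0 + acrophase)

    deterministic = config.dispersion == 0
    if not deterministic:
        if config.day_jitter_sd > 0:
            offsets = rng.normal(0, config.day_jitter_sd, config.days)
            lam = lam + np.repeat(offsets, MINUTES_PER_DAY)
        if config.hourly_env_sigma > 0:
            # hour-scale behavioural envelope: lognormal, mean 1, i.i.d. per
            # clock hour; leaves the cosine mean structure unbiased while
            # fragmenting the hourly profile like real wrist counts
            s = config.hourly_env_sigma
            env = rng.lognormal(-0.5 * s * s, s, config.days * 24)
            lam = lam * np.repeat(env, 60)
        n_events = rng.poisson(config.nap_rate * config.days)
        for _ in range(n_events):
            start = int(rng.integers(0, n_min))
            dur = int(15 + rng.exponential(config.event_duration_mean))
            stop = min(start + dur, n_min)
            base_here = mesor + amplitude * np.cos(
                2 * np.pi * t_hours[start] / 24.0 + acrophase
            )
            if base_here > mesor:  # daytime nap: near-total suppression
                lam[start:stop] *= 0.05
            else:  # nighttime arousal: activity burst
                lam[start:stop] += config.arousal_strength * max(amplitude, 0.25 * mesor)

    lam = np.maximum(lam, 0.0)
    if deterministic:
        counts = lam.copy()
    else:
        k = config.dispersion
        shape_rate = np.where(lam > 0, lam / k, 1.0)
        counts = rng.poisson(rng.gamma(k, shape_rate / 1.0) * (lam > 0)).astype(float)

    nonwear: list[tuple[int, int]] = []
    if not deterministic and config.nonwear_bouts_per_week > 0:
        n_bouts = rng.poisson(config.nonwear_bouts_per_week * config.days / 7.0)
        for _ in range(n_bouts):
            length = int(config.nonwear_bout_min + rng.exponential(config.nonwear_bout_extra_mean))
            start = int(rng.integers(0, max(n_min - length, 1)))
            stop = min(start + length, n_min)
            counts[start:stop] = 0.0
            nonwear.append((start, stop))

    series = EpochSeries(
        participant_id="",  # filled by caller
        start_time=pd.Timestamp(START_DATE),
        counts=counts,
    )
    return series, tuple(nonwear)


def simulate_cohort(config: SimulationConfig, out_dir: str | os.PathLike | None = None):
    """Generate a full cohort: actigraphy series, clinical records, truth.

    Returns ``(series_list, clinical_records, truths)``; when ``out_dir``
    is given, also writes one actigraphy CSV per participant, the
    clinical CSV, a ground-truth CSV and a YAML manifest of the config.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants + 1)
    cohort_rng = np.random.default_rng(streams[0])
    params = _draw_cohort_params(config, cohort_rng)

    series_list, records, truths = [], [], []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        prng = np.random.default_rng(streams[i + 1])
        series, nonwear = simulate_participant(
            config,
            prng,
            mesor=params["mesor"][i],
            amplitude=params["amplitude"][i],
            acrophase=params["acrophase"][i],
        )
        series = dataclasses.replace(series, participant_id=pid)
        record = ClinicalRecord(
            participant_id=pid,
            treatment="SSRI" if params["ssri"][i] else "PBO",
            sex="F" if params["female"][i] else "M",
            age=round(float(params["age"][i]), 1),
            hdrs_week0=int(params["hdrs0"][i]),
            hdrs_week1=int(params["hdrs1"][i]),
            hdrs_week8=int(params["hdrs8"][i]),
        )
        truth = GroundTruth(
            participant_id=pid,
            mesor=float(params["mesor"][i]),
            amplitude=float(params["amplitude"][i]),
            acrophase=float(params["acrophase"][i]),
            cq=float(params["cq"][i]),
            cq_std=float(params["cq_std"][i]),
            nonwear_intervals=nonwear,
            remitter=bool(params["hdrs8"][i] <= 7),
            week8_component="remit" if params["remit_component"][i] else "nonremit",
        )
        series_list.append(series)
        records.append(record)
        truths.append(truth)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for series in series_list:
            write_epoch_series(series, os.path.join(out_dir, f"{series.participant_id}.csv"))
        write_clinical_table(records, os.path.join(out_dir, "clinical.csv"))
        truth_rows = []
        for t in truths:
            row = dataclasses.asdict(t)
            row["nonwear_intervals"] = ";".join(f"{a}-{b}" for a, b in t.nonwear_intervals)
            truth_rows.append(row)
        pd.DataFrame(truth_rows).to_csv(os.path.join(out_dir, "truth.csv"), index=False)
        with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
            cfg = json.loads(json.dumps(dataclasses.asdict(config)))
            yaml.safe_dump({"config": cfg}, fh)

    return series_list, records, truths


def simulate_clinical_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Feature-level cohort table straight from ground-truth parameters.

    Skips minute-level signal synthesis and extraction: the standardized
    circadian measures in the returned table are the generator's own
    values.  This is the right input for checking that the statistical
    layer recovers the generating outcome coefficients free of any
    feature-measurement error, and it is orders of magnitude faster than
    the full pipeline for replicate studies.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    p = _draw_cohort_params(config, rng)
    n = config.n_participants
    acro = p["acrophase"]
    df = pd.DataFrame(
        {
            "cq": p["cq"],
            "acrophase": acro,
            "cq_std": p["cq_std"],
            "acrophase_std": (acro - acro.mean()) / acro.std(ddof=1),
            "ssri": p["ssri"],
            "female": p["female"].astype(float),
            "age": p["age"],
            "age_sq": p["age"] ** 2,
            "hdrs_week0": p["hdrs0"],
            "hdrs_week1": p["hdrs1"],
            "hdrs_week8": p["hdrs8"],
            "ln_hdrs_week0": np.log(p["hdrs0"]),
            "ln_hdrs_week1": np.log(p["hdrs1"]),
            "ln_hdrs_week8": np.log(p["hdrs8"]),
            "remitter": p["hdrs8"] <= 7,
        },
        index=pd.Index([f"P{i + 1:03d}" for i in range(n)], name="participant_id"),
    )
    return df
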