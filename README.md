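# actirhythm

Circadian rest-activity rhythm biomarkers from minute-epoch wrist
actigraphy, and the repeated-measures statistics that relate them to
change in depression severity during antidepressant treatment.

## Who this is for

Researchers working with wrist-worn activity monitors in clinical
populations — e.g. validating digital biomarkers of treatment response
in major depressive disorder. The package takes each participant from a
raw minute-by-minute activity-count series to a feature row of nine
circadian measures, joins those with a clinical table (treatment arm,
sex, age, Hamilton Depression Rating Scale scores at weeks 0/1/8), and
fits the standard inferential battery on top. A synthetic-cohort
generator with known ground truth makes the whole chain testable
without access to any clinical data.

## What it computes

**Preprocessing.** Non-wear is detected with the Choi zero-run rule: a
run of ≥ 90 consecutive zero-count minutes is non-wear, with nonzero
"artifact" bursts of ≤ 2 min absorbed when flanked by ≥ 30 min of zeros
on both sides. A valid day has ≥ 900 worn minutes (midnight to
midnight); participants need ≥ 4 valid days.

**Parametric measures.** The single-component cosinor model

    Y(t) = M + A·cos(2πt/τ + φ) + e(t),   τ = 24 h

is fitted by ordinary least squares after linearization
(x = cos 2πt/τ, z = sin 2πt/τ; β = A cos φ, γ = −A sin φ) over all worn
minutes of the recording, giving MESOR *M*, amplitude *A*, acrophase φ
(radians in (−2π, 0]; peak clock hour = −φτ/2π) and the circadian
quotient CQ = A/M.

**Nonparametric measures.** Per valid day, M10 and L5 are the mean
counts over the most active 600 and least active 300 consecutive
minutes; relative amplitude RA = (M10 − L5)/(M10 + L5). On hourly
means, intradaily variability IV = N Σ(xᵢ−xᵢ₋₁)² / [(N−1) Σ(xᵢ−x̄)²]
(≈ 2 for white noise) and interdaily stability
IS = N Σₕ(x̄ₕ−x̄)² / [s Σᵢ(xᵢ−x̄)²] (1 for a perfectly repeating day).

**Outcomes and inference.** Depression change is the log ratio
ΔHDRS_k = ln(week-k HDRS / baseline HDRS); remission is week-8 HDRS ≤ 7.
The statistical layer provides group descriptives with pooled t /
Mann-Whitney / Fisher tests, a Lilliefors normality check, a Spearman
screen of all nine measures against both outcomes, a repeated-measures
linear mixed model (response ln HDRS at week 0 and the horizon week,
random intercept per participant, REML, between-within denominator DF)
in which the measure × Week interactions quantify biomarker effects on
change, and a logistic remission model with an ROC-derived operating
threshold (maximizing TPR − FPR).

## Worked example

```python
from actirhythm import RunConfig, SimulationConfig, run_pipeline

res = run_pipeline(RunConfig(
    out_dir="demo",
    simulate=SimulationConfig(n_participants=40, days=7, seed=1),
))
print(res["counts"])
print(res["features"][["mesor", "amplitude", "cq", "acrophase", "ra", "iv", "is_"]].head(3).round(3))
print(res["mixed"][("parametric", "week1")].table.query("effect == 'cq_std:week'").round(4))
```

prints

```
{'read': 40, 'included': 40, 'features_computed': 40, 'modeled': 40}
                  mesor  amplitude     cq  acrophase     ra     iv    is_
participant_id
P001            147.106     88.474  0.601     -3.312  0.534  0.961  0.517
P002            225.715    210.779  0.934     -2.099  0.825  0.948  0.574
P003            151.938    122.823  0.808     -4.226  0.732  0.918  0.532
         effect  estimate      se       F  df_denom       p
12  cq_std:week    0.0824  0.0326  6.3946        33  0.0164
```

All 40 simulated participants pass the wear filters; each feature row
holds that participant's cosinor and nonparametric measures (e.g. P002
has a robust rhythm, CQ ≈ 0.93, peaking around 8 a.m.). The mixed-model
row is the biomarker effect of interest: the standardized-CQ × Week
interaction estimates how much less the log-HDRS of a participant 1 SD
higher in CQ falls over the first treatment week (here 0.082, F with
33 denominator DF, P ≈ 0.02 — the generator's true coefficient is
0.11). The same run writes `features.csv`, `outcomes.csv`,
`spearman.csv`, per-model coefficient tables, and `report.md` under
`demo/`.

The same flow is available from a shell:

```sh
actirhythm simulate --n 40 --days 7 --seed 1 --out demo-data
actirhythm analyze --input demo-data --clinical demo-data/clinical.csv --out demo
```

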