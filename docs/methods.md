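# Methods

## Data model

A participant's recording is a contiguous one-minute grid of
nonnegative activity counts, timezone-naive local clock time. Minutes
with no recorded row are explicit missing values, distinct from zero
counts: zeros drive non-wear detection, missing minutes do not, but
both are excluded from every measure. Days run midnight to midnight
throughout, so all clock-anchored quantities (acrophase, M10/L5 onset,
hourly bins) share one time origin. Daylight-saving transitions are out
of scope; the CSV dialects (documented in `actirhythm.io`) are package
conventions, not a vendor format.

## Non-wear detection and inclusion

The Choi rule is implemented over the run structure of the series:
maximal runs of zero (or missing) minutes are chained across nonzero
gaps of at most `artifact_max` = 2 min whenever the zero runs adjacent
to the gap are each at least `flank` = 30 min long; a chained span
totalling at least `window` = 90 min is non-wear. Flanking zeros are
required on *both* sides of an artifact — the canonical form of the
rule; a one-sided variant would let a single stray burst extend
non-wear indefinitely. Zero runs touching the series boundary qualify
with no interior context (devices are often unworn before first
donning). Non-wear minutes become missing values on the original grid
rather than being spliced out, so clock-time alignment survives
filtering.

A valid day has ≥ 900 worn minutes — exactly the 600-minute M10 plus
300-minute L5 windows, so both can be placed without forced overlap —
and a participant enters analysis with ≥ 4 valid days (4 × 1440 =
5760 min of potential recording). Inclusion is evaluated on valid days
only.

## Cosinor fit

One ordinary least-squares regression of all worn minutes (pooled
across the recording, typically ~10,000 points) on an intercept and the
cosine/sine pair at fixed 24-h period. Pooling across days, rather than
per-day fits averaged afterwards, matches treating the week as one
realization of a single underlying rhythm and is far more stable at
this epoch density. Amplitude and acrophase come from the coefficient
pair (A = √(β²+γ²); φ = atan2(−γ, β) mapped into (−2π, 0], so that a
mid-afternoon peak sits near −4.1 rad ≈ 15.6 h). Degenerate cases:
amplitude at numerical-noise scale (≤ 1e−10 relative to MESOR) sets a
degenerate-phase flag and reports φ = 0; MESOR ≤ 0 leaves CQ undefined
(NaN) with a warning; a design with rank < 3 (all observations at one
clock time) is an estimation error.

## Nonparametric measures

M10/L5 windows are day-bounded (no midnight crossing) and scanned at
every minute start; a window needs ≥ 75% observed minutes, and its
mean uses observed minutes only. Ties break to the earliest clock
start. Per-day window means are averaged over valid days and RA is
computed from the averaged M10 and L5. Hourly means require ≥ 30
observed minutes per hour. For IV, first-difference pairs spanning a
missing hour are dropped (a difference across a gap is not a one-hour
derivative), and the normalizations use realized pair/point counts;
for IS the hour-of-day means omit missing cells and `s` is the number
of hour bins with data. The 75%/30-min coverage thresholds are package
conventions. IV is not clipped to [0, 2]: the white-noise value is 2,
but alternating hourly data legitimately reaches 4.

## Outcomes

Change in depression is ln(week-k HDRS / baseline HDRS); remission is
week-8 HDRS ≤ 7. A zero post-baseline score is clamped to 0.5 before
the log (with a warning): it preserves ordering without discarding
exactly the participants who remitted fully. A zero baseline has no
meaningful ratio and is rejected. `pct_change` truncates the ratio
exp(Δ) to three decimals before differencing so that a printed ratio
and its percent change are always mutually consistent
(Δ = −0.176 → 0.838 → −16.2%).

## Statistical layer

Standardized measure columns are z-scores across included participants
(sample SD). Group comparisons use the pooled-variance t-test
(DF = n₁+n₂−2), a tie-corrected normal z for the Mann-Whitney U, and
Fisher's exact test for binaries. Normality of the log-change outcomes
uses the Lilliefors variant of the Kolmogorov-Smirnov test (null
parameters are estimated from the sample); beyond the table range the
p-value is reported as a bound ("> 0.15"). The Spearman screen runs 9
measures × 2 outcomes with no multiplicity correction; the result
carries the test count, and a `drop_ids` re-run supports outlier
robustness checks.

The repeated-measures model is a linear mixed model on the long layout
(ln HDRS at week 0 and the horizon week; exactly 2 rows per
participant), REML, random intercept per participant — with two
timepoints this is equivalent to any compound-symmetric structure with
nonnegative intra-class correlation. Fixed effects: treatment, sex,
age, age² (uncentered), the standardized measures of the chosen set,
Week, and every × Week interaction. F statistics are squared Wald t's;
denominator DF follow the between-within (containment) rule — effects
constant within participant get n_subj − q_between, Week-varying
effects get n_obs − n_subj − q_within. For 40 participants with the
parametric measure set both strata give 33. Satterthwaite
approximations were considered and not used: the between-within rule
is exact for this balanced two-timepoint design and reproduces the
design DF deterministically. A singular fit (non-finite standard
errors) is an error with variance-component diagnostics.

The logistic remission model is a maximum-likelihood fit of remitter on
the predictor set plus the four covariates. The operating threshold
maximizes TPR − FPR on the in-sample ROC, smallest threshold on ties;
predicted-positive means fitted probability ≥ threshold. "Weighted
accuracy" is the overall proportion correct, (TP+TN)/total — the only
reading consistent with reporting it alongside sensitivity and
specificity on unbalanced groups. Perfect separation (or a collinear
design) falls back to a faintly ridge-penalized fit, and as a last
resort the null model; the report flags separation and always
recomputes its percentages from the stored confusion counts.

## Synthetic cohort generator

The generator emulates a 40-participant, 4–7-day actigraphy add-on to
a two-arm placebo-controlled antidepressant trial. Per participant:
MESOR lognormal (median 200 counts/min, σ = 0.45), CQ truncated normal
(mean 0.80, SD 0.18, bounds [0.05, 1.2]), acrophase normal (−4.1 ±
0.9 rad). Minute intensity is the cosine plus three behavioural noise
layers, each with its own knob:

* an i.i.d. lognormal mean-1 *hourly envelope* (σ = 0.45) — hour-scale
  behavioural fluctuation, the main driver of realistic IV;
* additive per-day offsets (SD 20 counts/min) — day-to-day level
  jitter, which depresses IS;
* nap/arousal events (0.75/day, ~60 min): daytime naps suppress
  intensity to 5%, nighttime arousals add 0.25 × amplitude.

Counts are gamma-Poisson (negative binomial) with dispersion 3;
non-wear bouts (1/week, 90 min + exponential tail) overwrite counts
with zeros. Setting `dispersion = 0` disables every stochastic layer
and emits the truncated cosine itself for exact-recovery tests.
`hdrs_week0` is normal (17.8 ± 4.8, rounded, clipped to [8, 35]); the
week-1 score follows ln W1 = ln W0 − 0.11 + 0.11·CQ_std − 0.14·SSRI +
ε (ε SD 0.18), and week 8 is a two-component mixture (40% strongly
improving, drift −1.39 ± 0.45; else −0.32 ± 0.30) independent of
week-1 circadian features by default, so remission labels emerge from
the scores. All randomness descends from one seed via SeedSequence
spawning (stream 0 for cohort-level draws, stream i+1 for participant
i), making cohorts bit-reproducible, and the clinical-only fast path
(`simulate_clinical_cohort`) draws from the same stream as the full
generator, so both agree on every clinical value.

The noise defaults were chosen so that a default cohort's feature
summary lands within the published case mix this generator emulates
(MESOR ≈ 220, CQ ≈ 0.78, IV ≈ 1.07, IS ≈ 0.5, RA ≈ 0.68) while true
vs. estimated CQ still correlate at Spearman ≈ 0.92. These two goals
pull in opposite directions — more day-to-day noise gives lower,
more realistic IS but noisier CQ estimates — and the defaults sit at
the compromise that satisfies both. What the generator does *not*
emulate: autocorrelated within-hour microstructure, weekday/weekend
structure, seasonal light effects, or device-specific count
transfer functions. Passing tests on this data therefore demonstrate
correctness of the measures and models under a cosine-plus-noise
world, not device-level validity on real wrists.

## Problem sizes in the test suite

Replicate studies use sizes chosen for tight-but-fast Monte Carlo
checks: coefficient-recovery properties run 150–500 cohorts of n = 40
through the clinical-level fast path (the minute-level signal layer
adds only feature-measurement noise, which is exercised separately at
small replicate counts), the white-noise IV check uses 200 replicates
of 10,000 hourly points, and brute-force oracle comparisons cover
series up to 10 days. The full suite runs in about a minute.

## Known limitations

* The Choi implementation treats parameters as fixed minutes; it does
  not implement the Troiano or van Hees alternatives.
* The mixed model's between-within DF rule is exact for the balanced
  two-timepoint design it is used on; unbalanced designs would need
  Satterthwaite or Kenward-Roger machinery not implemented here.
* Logistic metrics are in-sample, as in the design this mirrors; no
  cross-validation is provided.
* HDRS trajectories are generated on the log scale with rounding; very
  low baselines (< 8) are outside the generator's default range.
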