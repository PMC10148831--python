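"""Statistical layer linking circadian measures to depression change.

The workflow mirrors a standard repeated-measures biomarker validation:

1. descriptive group comparisons by remission status (pooled-variance
   t-tests, Mann-Whitney U with a tie-corrected normal z, Fisher's exact
   test for binaries);
2. a Lilliefors-type Kolmogorov-Smirnov normality check of the
   log-change outcomes;
3. a Spearman rank-correlation screen of each circadian measure against
   the week-1 and week-8 log changes (no multiplicity correction; the
   report carries the number of tests);
4. a repeated-measures linear mixed model: response ln(HDRS) at week 0
   and the horizon week, random intercept per participant, REML, fixed
   effects treatment, sex, age, age^2, the standardized measures of the
   chosen set, Week, and every x Week interaction.  The measure x Week
   coefficients quantify how the biomarker relates to *change* in
   depression.  F tests use the between-within (containment)
   denominator-DF rule;
5. a logistic model of week-8 remission with an in-sample ROC, the
   operating threshold maximizing TPR - FPR (smallest on ties), and
   confusion-matrix metrics at that threshold.

Standardized measure columns are z-scores across included participants
(sample SD, ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .outcomes import ZERO_SCORE_CLAMP, classify_remission, delta_hdrs

__all__ = [
    "MEASURE_COLUMNS",
    "MEASURE_SETS",
    "MixedModelResult",
    "ClassifierReport",
    "standardize",
    "build_cohort_table",
    "describe_and_compare",
    "ks_normality",
    "spearman_screen",
    "fit_rm_anova",
    "fit_logistic_remission",
    "confusion_metrics",
]

MEASURE_COLUMNS = [
    "mesor",
    "amplitude",
    "cq",
    "acrophase",
    "m10",
    "l5",
    "ra",
    "iv",
    "is_",
]
# measures that enter models standardized
STANDARDIZED = ["cq", "acrophase", "ra", "iv", "is_"]
MEASURE_SETS = {
    "parametric": ["cq_std", "acrophase_std"],
    "nonparametric": ["ra_std", "iv_std", "is_std"],
}
COVARIATES = ["ssri", "female", "age", "age_sq"]


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed-effect table of the repeated-measures mixed model."""

    table: pd.DataFrame  # effect, estimate, se, F, df_denom, p
    method: str
    n_obs: int
    n_participants: int
    converged: bool
    random_intercept_var: float
    residual_var: float

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


@dataclass(frozen=True)
class ClassifierReport:
    coefficients: pd.Series
    threshold: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # all five metrics in percent
    specificity: float
    weighted_accuracy: float
    ppv: float
    npv: float
    perfect_separation: bool = False


def standardize(values: pd.Series | np.ndarray) -> np.ndarray:
    """z-scores with the sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _safe_log(scores: pd.Series) -> np.ndarray:
    x = np.asarray(scores, dtype=float)
    return np.log(np.where(x == 0, ZERO_SCORE_CLAMP, x))


def build_cohort_table(features: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Join circadian features with clinical covariates and outcomes.

    Both inputs are indexed by participant_id; only participants present
    in both (i.e. included by the wear filters) are kept.  Adds dummy
    codings (ssri, female), age_sq, standardized measure columns,
    log-HDRS values per week, log-change outcomes, and remission labels.
    """
    df = features.join(clinical, how="inner")
    if df.empty:
        raise ValueError("no participants present in both features and clinical table")
    df = df.copy()
    df["ssri"] = (df["treatment"] == "SSRI").astype(float)
    df["female"] = (df["sex"] == "F").astype(float)
    df["age"] = df["age"].astype(float)
    df["age_sq"] = df["age"] ** 2
    for col in STANDARDIZED:
        df[f"{col.rstrip('_')}_std"] = standardize(df[col])
    for wk in (0, 1, 8):
        df[f"ln_hdrs_week{wk}"] = _safe_log(df[f"hdrs_week{wk}"])
    df["delta_hdrs1"] = [
        delta_hdrs(k, b) for k, b in zip(df["hdrs_week1"], df["hdrs_week0"])
    ]
    df["delta_hdrs8"] = [
        delta_hdrs(k, b) for k, b in zip(df["hdrs_week8"], df["hdrs_week0"])
    ]
    df["remitter"] = [classify_remission(v) for v in df["hdrs_week8"]]
    return df


def _mannwhitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal-approximation z for the Mann-Whitney U."""
    n1, n2 = len(a), len(b)
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    if sigma == 0:
        return 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / sigma
    return float(z), float(2 * stats.norm.sf(abs(z)))


def describe_and_compare(
    cohort: pd.DataFrame,
    numeric_vars: list[str],
    binary_vars: list[str] | None = None,
    group_col: str = "remitter",
) -> pd.DataFrame:
    """Group descriptives with two-sample tests, one row per variable.

    Numeric variables get mean (SD), median (IQR = p75 - p25) per group,
    a pooled-variance t-test with DF = n1 + n2 - 2, and the Mann-Whitney
    z.  Binary variables get counts and Fisher's exact p.
    """
    g0 = cohort[~cohort[group_col].astype(bool)]
    g1 = cohort[cohort[group_col].astype(bool)]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 participants")
    rows = []
    for var in numeric_vars:
        a = g0[var].to_numpy(dtype=float)
        b = g1[var].to_numpy(dtype=float)
        t_res = stats.ttest_ind(a, b, equal_var=True)
        z, z_p = _mannwhitney_z(a, b)
        rows.append(
            {
                "variable": var,
                "kind": "numeric",
                "group0_mean": a.mean(),
                "group0_sd": a.std(ddof=1),
                "group0_median": np.median(a),
                "group0_iqr": np.percentile(a, 75) - np.percentile(a, 25),
                "group1_mean": b.mean(),
                "group1_sd": b.std(ddof=1),
                "group1_median": np.median(b),
                "group1_iqr": np.percentile(b, 75) - np.percentile(b, 25),
                "t": float(t_res.statistic),
                "t_df": len(a) + len(b) - 2,
                "t_p": float(t_res.pvalue),
                "mwu_z": z,
                "mwu_p": z_p,
            }
        )
    for var in binary_vars or []:
        a = g0[var].astype(bool)
        b = g1[var].astype(bool)
        table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        _, p = stats.fisher_exact(table)
        rows.append(
            {
                "variable": var,
                "kind": "binary",
                "group0_n_true": table[0][0],
                "group0_n": len(a),
                "group1_n_true": table[1][0],
                "group1_n": len(b),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows)


def ks_normality(values: np.ndarray, alpha: float = 0.05):
    """Kolmogorov-Smirnov normality check with estimated mean and SD.

    Because the null parameters are estimated from the sample, the
    Lilliefors correction is used for the p-value; beyond the table
    range the p is reported as the bound (displayed as "> 0.15").
    Returns ``(D, p, passed, display)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("normality check needs n >= 5")
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    passed = p > alpha
    display = "> 0.15" if p >= 0.15 else f"{p:.3f}"
    return float(d), float(p), bool(passed), display


def spearman_screen(
    cohort: pd.DataFrame,
    measures: list[str] = MEASURE_COLUMNS,
    outcomes: tuple[str, ...] = ("delta_hdrs1", "delta_hdrs8"),
    drop_ids: list | None = None,
) -> pd.DataFrame:
    """Spearman rank correlation of each measure with each outcome.

    ``drop_ids`` re-runs the screen without the listed participants
    (an outlier-robustness check).  p-values use the two-sided t
    approximation; ties get average ranks.  No multiplicity correction
    is applied; ``n_tests`` records how many correlations were run.
    """
    df = cohort.drop(index=drop_ids) if drop_ids else cohort
    if len(df) < 4:
        raise ValueError("Spearman screen needs n >= 4")
    rows = []
    for m in measures:
        for out in outcomes:
            r = stats.spearmanr(df[m], df[out])
            rows.append(
                {
                    "measure": m,
                    "outcome": out,
                    "r_s": float(r.statistic),
                    "p": float(r.pvalue),
                    "n": len(df),
                }
            )
    result = pd.DataFrame(rows)
    result.attrs["n_tests"] = len(result)
    return result


def _long_form(cohort: pd.DataFrame, measure_cols: list[str], horizon: str):
    """Stack week 0 and the horizon week into the repeated-measures layout."""
    if horizon not in ("week1", "week8"):
        raise ValueError("horizon must be 'week1' or 'week8'")
    endpoint = f"ln_hdrs_{horizon}"
    frames = []
    for week, resp in ((0.0, "ln_hdrs_week0"), (1.0, endpoint)):
        part = cohort[COVARIATES + measure_cols].copy()
        part["week"] = week
        part["ln_hdrs"] = cohort[resp]
        part["participant"] = cohort.index
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


def fit_rm_anova(
    cohort: pd.DataFrame, measure_set: str = "parametric", horizon: str = "week1"
) -> MixedModelResult:
    """Repeated-measures mixed model of log HDRS at week 0 vs the horizon.

    Random intercept per participant, REML estimation.  Each fixed
    effect's F statistic is the square of its Wald t; denominator DF
    follow the between-within rule: effects constant within participant
    get ``n_subj - q_between`` and Week-varying effects get
    ``n_obs - n_subj - q_within`` (q counts the parameters of that
    stratum, the intercept belonging to the between stratum).
    """
    measure_cols = MEASURE_SETS[measure_set]
    if cohort.index.size < 10:
        raise ValueError("mixed model needs at least 10 participants")
    base = COVARIATES + measure_cols
    if cohort[base].isna().any().any():
        raise ValueError("missing covariate or measure values")
    long = _long_form(cohort, measure_cols, horizon)

    between = list(base)
    within = ["week"] + [f"{c}:week" for c in base]
    X = pd.DataFrame(index=long.index)
    X["intercept"] = 1.0
    for c in between:
        X[c] = long[c]
    X["week"] = long["week"]
    for c in base:
        X[f"{c}:week"] = long[c] * long["week"]

    model = sm.MixedLM(
        endog=long["ln_hdrs"].to_numpy(),
        exog=X,
        groups=long["participant"].to_numpy(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    if not np.all(np.isfinite(fit.bse_fe)):
        raise RuntimeError(
            "mixed model fit is singular: non-finite standard errors; "
            f"cov_re={float(fit.cov_re.iloc[0, 0]):.3g}, scale={fit.scale:.3g}"
        )

    n_subj = cohort.index.size
    n_obs = len(long)
    q_between = len(between) + 1  # + intercept
    q_within = len(within)
    df_between = n_subj - q_between
    df_within = n_obs - n_subj - q_within

    rows = []
    for name in X.columns:
        est = float(fit.fe_params[name])
        se = float(fit.bse_fe[name])
        f_stat = (est / se) ** 2 if se > 0 else np.inf
        ddf = df_between if name in (["intercept"] + between) else df_within
        rows.append(
            {
                "effect": name,
                "estimate": est,
                "se": se,
                "F": f_stat,
                "df_denom": ddf,
                "p": float(stats.f.sf(f_stat, 1, ddf)),
            }
        )
    return MixedModelResult(
        table=pd.DataFrame(rows),
        method="REML",
        n_obs=n_obs,
        n_participants=n_subj,
        converged=bool(fit.converged),
        random_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
    )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, weighted accuracy, PPV, NPV in percent.

    Weighted accuracy is the overall proportion of correct predictions,
    (TP + TN) / total.
    """
    total = tp + fp + tn + fn
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "weighted_accuracy": 100.0 * (tp + tn) / total if total else float("nan"),
        "ppv": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "npv": 100.0 * tn / (tn + fn) if tn + fn else float("nan"),
    }


def fit_logistic_remission(
    cohort: pd.DataFrame, predictors: list[str], include_covariates: bool = True
) -> ClassifierReport:
    """Logistic model of week-8 remission with ROC-derived threshold.

    Maximum-likelihood fit of remitter on the predictors (plus the
    treatment/sex/age/age^2 covariates by default); the in-sample ROC
    yields the operating threshold maximizing TPR - FPR, smallest such
    threshold on ties; predicted-positive means fitted probability >=
    threshold.  Perfect separation is flagged and metrics still come
    from the separating fit.
    """
    from sklearn.metrics import roc_curve

    y = cohort["remitter"].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("both remission classes must be present")
    cols = list(predictors) + (COVARIATES if include_covariates else [])
    X = sm.add_constant(cohort[cols].astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = None
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=500)
        except Exception:
            # perfect separation (or collinearity) aborts Newton; try a
            # faintly penalized refit, else fall back to the null model
            try:
                fit = sm.Logit(y, X).fit_regularized(alpha=1e-6, disp=0, maxiter=500)
            except Exception:
                fit = None
    if fit is not None:
        params = pd.Series(np.asarray(fit.params), index=X.columns)
        prob = np.asarray(fit.predict(X))
    else:
        params = pd.Series(np.nan, index=X.columns)
        params["const"] = float(np.log(y.mean() / (1 - y.mean())))
        prob = np.full(y.size, y.mean())
    separated = set(np.round(prob, 6)) <= {0.0, 1.0}

    fpr, tpr, thresholds = roc_curve(y, prob)
    j = tpr - fpr
    best = j == j.max()
    threshold = float(np.min(thresholds[best]))
    pred = prob >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    metrics = confusion_metrics(tp, fp, tn, fn)
    return ClassifierReport(
        coefficients=params,
        threshold=threshold,
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=thresholds,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        perfect_separation=separated,
        **metrics,
    )
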