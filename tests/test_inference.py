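import numpy as np
import pandas as pd
import pytest
from scipy import stats

from actirhythm.inference import (
    MEASURE_SETS,
    build_cohort_table,
    confusion_metrics,
    describe_and_compare,
    fit_logistic_remission,
    fit_rm_anova,
    ks_normality,
    spearman_screen,
    standardize,
)
from actirhythm.simulate import SimulationConfig, simulate_clinical_cohort
from oracles import fisher_exact_oracle, spearman_oracle


def _toy_cohort(n0=24, n1=16, seed=0):
    """Hand-built cohort frame with a binary remission split."""
    rng = np.random.default_rng(seed)
    n = n0 + n1
    df = pd.DataFrame(
        {
            "age": rng.normal(30, 10, n).clip(18, 64),
            "cq": rng.normal(0.8, 0.15, n),
            "ssri": rng.random(n) < 0.5,
            "female": rng.random(n) < 0.7,
            "remitter": [False] * n0 + [True] * n1,
        },
        index=[f"P{i}" for i in range(n)],
    )
    return df


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = standardize(np.array([1.0, 4.0, 2.0, 8.0, 5.0]))
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10

    def test_idempotence(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        np.testing.assert_allclose(standardize(standardize(x)), standardize(x), atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones(5))


class TestDescribeAndCompare:
    def test_t_test_df_for_24_vs_16(self):
        table = describe_and_compare(_toy_cohort(), numeric_vars=["age", "cq"])
        assert (table["t_df"] == 38).all()

    def test_identical_groups_give_t_zero(self):
        df = _toy_cohort(20, 20)
        df["age"] = list(range(20)) + list(range(20))
        row = describe_and_compare(df, numeric_vars=["age"]).iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["mwu_z"] == pytest.approx(0.0, abs=1e-12)

    def test_fisher_matches_hypergeometric_enumeration(self):
        # SSRI by remission: 16/8 vs 6/10
        df = _toy_cohort(24, 16)
        df.loc[df.index[:16], "ssri"] = True
        df.loc[df.index[16:24], "ssri"] = False
        df.loc[df.index[24:30], "ssri"] = True
        df.loc[df.index[30:], "ssri"] = False
        table = describe_and_compare(df, numeric_vars=[], binary_vars=["ssri"])
        expected = fisher_exact_oracle([[16, 8], [6, 10]])
        assert table.iloc[0]["fisher_p"] == pytest.approx(expected, abs=1e-10)

    def test_tiny_group_rejected(self):
        df = _toy_cohort(30, 1)
        with pytest.raises(ValueError):
            describe_and_compare(df, numeric_vars=["age"])


class TestKsNormality:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(1)
        passes = sum(
            ks_normality(rng.normal(size=40))[2] for _ in range(500)
        )
        assert passes >= 0.90 * 500

    def test_exponential_samples_mostly_fail(self):
        rng = np.random.default_rng(2)
        fails = sum(
            not ks_normality(rng.exponential(size=40))[2] for _ in range(500)
        )
        assert fails >= 0.80 * 500

    def test_d_statistic_is_max_cdf_gap(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        d, *_ = ks_normality(x)
        xs = np.sort(x)
        f = stats.norm.cdf(xs, loc=x.mean(), scale=x.std(ddof=1))
        n = len(x)
        gaps = np.maximum(np.arange(1, n + 1) / n - f, f - np.arange(0, n) / n)
        assert d == pytest.approx(gaps.max(), abs=1e-12)

    def test_large_p_displayed_as_bound(self):
        rng = np.random.default_rng(3)
        *_, display = ks_normality(rng.normal(size=200))
        assert display == "> 0.15"


class TestSpearmanScreen:
    def _cohort_with_outcomes(self, x, y1):
        df = pd.DataFrame({"cq": x, "delta_hdrs1": y1, "delta_hdrs8": y1})
        return df

    def test_monotone_transform_gives_one(self):
        x = np.linspace(-2, 2, 12)
        res = spearman_screen(
            self._cohort_with_outcomes(x, x**3), measures=["cq"]
        )
        assert res["r_s"].iloc[0] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.linspace(0, 5, 9)
        res = spearman_screen(self._cohort_with_outcomes(x, -x), measures=["cq"])
        assert res["r_s"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0]
        y = [3.0, 1.0, 1.0, 2.0]
        res = spearman_screen(self._cohort_with_outcomes(x, y), measures=["cq"])
        assert res["r_s"].iloc[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_outlier_removal_changes_n(self):
        x = np.arange(10.0)
        df = self._cohort_with_outcomes(x, x)
        res = spearman_screen(df, measures=["cq"], drop_ids=[0, 1])
        assert (res["n"] == 8).all()


class TestMixedModel:
    def test_denominator_df_is_33_for_parametric_set(self):
        cohort = simulate_clinical_cohort(SimulationConfig(seed=1))
        res = fit_rm_anova(cohort, "parametric", "week1")
        assert (res.table["df_denom"] == 33).all()
        assert res.n_obs == 80
        assert res.n_participants == 40
        assert res.method == "REML"

    def test_interaction_recovery_across_generator_coefficients(self):
        # the biomarker-by-week coefficient is recovered without bias
        for beta in (-0.2, 0.0, 0.3):
            ests = []
            for seed in range(150):
                cohort = simulate_clinical_cohort(
                    SimulationConfig(seed=seed, beta_cq_week=beta)
                )
                res = fit_rm_anova(cohort, "parametric", "week1")
                ests.append(res.effect("cq_std:week")["estimate"])
            ests = np.asarray(ests)
            mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
            assert abs(ests.mean() - beta) < 2 * mc_se + 1e-12, (
                f"beta={beta}: mean {ests.mean():.4f}, MC-SE {mc_se:.4f}"
            )

    def test_week8_horizon_uses_week8_response(self):
        cohort = simulate_clinical_cohort(SimulationConfig(seed=5))
        res1 = fit_rm_anova(cohort, "parametric", "week1")
        res8 = fit_rm_anova(cohort, "parametric", "week8")
        # week-8 change is much larger than week-1 change
        assert res8.effect("week")["estimate"] < res1.effect("week")["estimate"]


class TestLogistic:
    def test_metrics_recompute_from_confusion_counts(self):
        m = confusion_metrics(tp=15, fn=1, tn=12, fp=12)
        assert m["sensitivity"] == pytest.approx(93.75)
        assert m["specificity"] == pytest.approx(50.00)
        assert m["weighted_accuracy"] == pytest.approx(67.50)
        assert m["ppv"] == pytest.approx(55.5556, abs=1e-3)
        assert m["npv"] == pytest.approx(92.3077, abs=1e-3)

    def test_separable_predictor_classifies_perfectly(self):
        rng = np.random.default_rng(0)
        n = 20
        df = pd.DataFrame(
            {
                "score": np.r_[rng.normal(3, 0.1, 10), rng.normal(-3, 0.1, 10)],
                "remitter": [True] * 10 + [False] * 10,
            }
        )
        rep = fit_logistic_remission(df, ["score"], include_covariates=False)
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0
        assert rep.perfect_separation

    def test_constant_predictor_gives_diagonal_roc(self):
        df = pd.DataFrame(
            {"score": np.ones(20), "remitter": [True] * 8 + [False] * 12}
        )
        rep = fit_logistic_remission(df, ["score"], include_covariates=False)
        j = rep.roc_tpr - rep.roc_fpr
        np.testing.assert_allclose(j, 0.0, atol=1e-12)

    def test_report_metrics_match_stored_counts(self, ):
        cohort = build_cohort_table_fixture()
        rep = fit_logistic_remission(cohort, MEASURE_SETS["parametric"])
        m = confusion_metrics(rep.tp, rep.fp, rep.tn, rep.fn)
        assert rep.sensitivity == m["sensitivity"]
        assert rep.weighted_accuracy == m["weighted_accuracy"]
        assert rep.threshold in rep.roc_thresholds


def build_cohort_table_fixture():
    """Cohort table via the public builder from simulated features."""
    rng = np.random.default_rng(8)
    n = 30
    features = pd.DataFrame(
        {
            "mesor": rng.normal(200, 60, n),
            "amplitude": rng.normal(160, 50, n),
            "cq": rng.normal(0.8, 0.15, n),
            "acrophase": rng.normal(-4.1, 0.8, n),
            "m10": rng.normal(320, 100, n),
            "l5": rng.gamma(2, 20, n),
            "ra": rng.uniform(0.4, 0.95, n),
            "iv": rng.uniform(0.5, 1.6, n),
            "is_": rng.uniform(0.1, 0.6, n),
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="participant_id"),
    )
    clinical = pd.DataFrame(
        {
            "treatment": rng.permuted(["SSRI", "PBO"] * (n // 2)),
            "sex": np.where(rng.random(n) < 0.7, "F", "M"),
            "age": rng.normal(31, 10, n).clip(18, 64),
            "hdrs_week0": rng.integers(10, 30, n),
            "hdrs_week1": rng.integers(8, 25, n),
            "hdrs_week8": rng.integers(1, 25, n),
        },
        index=features.index,
    )
    return build_cohort_table(features, clinical)


class TestCohortTable:
    def test_standardized_columns_and_outcomes(self):
        cohort = build_cohort_table_fixture()
        for col in ["cq_std", "acrophase_std", "ra_std", "iv_std", "is_std"]:
            assert abs(cohort[col].mean()) < 1e-10
            assert abs(cohort[col].std(ddof=1) - 1) < 1e-10
        np.testing.assert_allclose(
            cohort["delta_hdrs1"],
            np.log(cohort["hdrs_week1"] / cohort["hdrs_week0"]),
        )
        assert (cohort["remitter"] == (cohort["hdrs_week8"] <= 7)).all()
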