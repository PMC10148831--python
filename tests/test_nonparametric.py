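import numpy as np
import pytest

from actirhythm.nonparametric import (
    compute_is,
    compute_iv,
    compute_m10_l5_ra,
    hourly_bin,
    nonparametric_summary,
    window_activity,
)
from actirhythm.preprocess import detect_nonwear_choi
from conftest import make_series
from oracles import is_oracle, iv_oracle, window_mean_oracle


def _block_day(high=400.0, low=10.0):
    """High activity on [8h, 20h), low elsewhere, fully worn."""
    day = np.full(1440, low)
    day[8 * 60 : 20 * 60] = high
    return day


class TestWindowActivity:
    def test_block_day_m10_l5(self):
        day = _block_day()
        m10, s10 = window_activity(day, 600, "most")
        l5, s5 = window_activity(day, 300, "least")
        assert m10 == pytest.approx(400.0)
        assert s10 == 8 * 60  # earliest start inside the high block
        assert l5 == pytest.approx(10.0)
        assert s5 == 0  # earliest of the tied low windows

    def test_constant_day(self):
        day = np.full(1440, 100.0)
        assert window_activity(day, 600, "most")[0] == pytest.approx(100.0)
        assert window_activity(day, 300, "least")[0] == pytest.approx(100.0)

    def test_insufficient_coverage_returns_missing(self):
        day = np.full(1440, np.nan)
        day[:400] = 50.0  # best 600-min window has 400 observed < 75%
        mean, start = window_activity(day, 600, "most")
        assert np.isnan(mean) and np.isnan(start)

    @pytest.mark.parametrize("width, mode", [(600, "most"), (300, "least")])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_scan(self, width, mode, seed):
        rng = np.random.default_rng(seed)
        day = rng.integers(0, 500, 1440).astype(float)
        day[rng.random(1440) < 0.2] = np.nan
        mean, start = window_activity(day, width, mode)
        omean, ostart = window_mean_oracle(day, width, mode)
        assert mean == pytest.approx(omean, abs=1e-10)
        assert start == ostart


class TestM10L5RA:
    def _series(self, day, days=7):
        return make_series(np.tile(day, days))

    def test_ra_from_block_days(self):
        series = self._series(_block_day(300.0, 100.0))
        profile = detect_nonwear_choi(series)
        m10, l5, ra, m10_on, l5_on = compute_m10_l5_ra(series, profile)
        assert m10 == pytest.approx(300.0)
        assert l5 == pytest.approx(100.0)
        assert ra == pytest.approx(0.5)
        assert m10_on == pytest.approx(8.0)

    def test_ra_zero_for_constant_activity(self):
        series = self._series(np.full(1440, 100.0))
        profile = detect_nonwear_choi(series)
        *_, ra, _, _ = (*compute_m10_l5_ra(series, profile),)
        assert ra == pytest.approx(0.0, abs=1e-12)

    def test_ra_one_when_l5_is_zero(self):
        # a truly motionless night: wear established externally (an
        # all-wear profile), so the zero block stays in the data
        from actirhythm.preprocess import WearProfile

        day = np.full(1440, 200.0)
        day[:300] = 0.0
        series = self._series(day)
        profile = WearProfile(
            participant_id=series.participant_id,
            wear_mask=np.ones(len(series), dtype=bool),
            valid_days=tuple(sorted({ts.date() for ts in series.timestamps})),
        )
        m10, l5, ra, *_ = compute_m10_l5_ra(series, profile)
        assert l5 == pytest.approx(0.0)
        assert ra == pytest.approx(1.0)

    def test_900_minute_day_supports_disjoint_windows(self):
        # exactly 900 worn minutes: M10 and L5 windows both defined
        day = np.full(1440, np.nan)
        day[:600] = 300.0
        day[600:900] = 20.0
        series = self._series(day, days=4)
        profile = detect_nonwear_choi(series)
        assert len(profile.valid_days) == 4
        m10, l5, ra, *_ = compute_m10_l5_ra(series, profile)
        assert m10 == pytest.approx(300.0)
        assert l5 == pytest.approx(20.0)


class TestHourlyBin:
    def test_full_week_gives_168_hours(self):
        series = make_series(np.full(7 * 1440, 120.0))
        hourly = hourly_bin(series, detect_nonwear_choi(series))
        assert hourly.values.size == 168
        assert hourly.n_observed == 168
        np.testing.assert_allclose(hourly.values, 120.0)

    def test_sparse_hour_is_missing(self):
        counts = np.full(2 * 1440, 50.0)
        counts[60:110] = np.nan  # hour 1 of day 1 has only 10 observed minutes
        series = make_series(counts)
        hourly = hourly_bin(series, detect_nonwear_choi(series))
        assert np.isnan(hourly.values[1])
        assert hourly.values[2] == pytest.approx(50.0)


class TestIV:
    def test_alternating_series_is_exactly_four(self):
        x = np.tile([10.0, 30.0], 84)  # N = 168
        assert compute_iv(x) == pytest.approx(4.0, abs=1e-12)

    def test_smooth_sinusoid_is_near_zero(self):
        n = 168
        x = np.sin(2 * np.pi * np.arange(n) / 24.0)
        iv = compute_iv(x)
        assert iv == pytest.approx(iv_oracle(x), abs=1e-12)
        assert iv == pytest.approx(0.0685, abs=5e-3)  # 4*sin^2(pi/24) scale
        assert iv < 0.1

    def test_gaussian_noise_near_two(self):
        rng = np.random.default_rng(11)
        ivs = [compute_iv(rng.normal(size=2000)) for _ in range(50)]
        assert np.mean(ivs) == pytest.approx(2.0, abs=0.05)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.random(200)
        assert compute_iv(3.5 * x + 40) == pytest.approx(compute_iv(x), rel=1e-12)

    def test_gap_pairs_dropped_matches_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.random(240)
        x[rng.random(240) < 0.15] = np.nan
        assert compute_iv(x) == pytest.approx(iv_oracle(x), abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(compute_iv(np.full(24, 7.0)))


class TestIS:
    def test_identical_days_give_one(self):
        profile = np.arange(24, dtype=float)
        x = np.tile(profile, 7)
        assert compute_is(x) == pytest.approx(1.0, abs=1e-12)

    def test_iid_noise_near_one_over_days(self):
        rng = np.random.default_rng(21)
        vals = [compute_is(rng.normal(size=7 * 24)) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(1 / 7, abs=0.02)

    def test_two_day_offset_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        day = rng.random(24)
        x = np.concatenate([day, day + 5.0])
        assert compute_is(x) == pytest.approx(is_oracle(x), abs=1e-12)

    def test_missing_hours_match_bruteforce(self):
        rng = np.random.default_rng(13)
        x = rng.random(7 * 24) + np.tile(np.sin(np.arange(24) / 4), 7)
        x[rng.random(168) < 0.2] = np.nan
        assert compute_is(x) == pytest.approx(is_oracle(x), abs=1e-12)

    def test_bounds_and_affine_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.random(5 * 24) * 100
            v = compute_is(x)
            assert 0.0 <= v <= 1.0
            assert compute_is(2.0 * x + 7) == pytest.approx(v, rel=1e-10)


class TestEndToEndSummary:
    def test_oracle_equivalence_on_masked_series(self):
        rng = np.random.default_rng(17)
        days = 6
        t = np.arange(days * 1440) / 60.0
        lam = 200 + 150 * np.cos(2 * np.pi * t / 24 - 4.0)
        counts = rng.poisson(np.maximum(lam, 0)).astype(float)
        counts[3000:3200] = 0.0  # non-wear bout
        series = make_series(counts)
        profile = detect_nonwear_choi(series)
        summary = nonparametric_summary(series, profile)
        hourly = hourly_bin(series, profile)
        assert summary.iv == pytest.approx(iv_oracle(hourly.values), abs=1e-10)
        assert summary.is_ == pytest.approx(is_oracle(hourly.values), abs=1e-10)
        assert 0 <= summary.ra <= 1
        assert summary.l5 <= summary.m10
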