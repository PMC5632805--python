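"""Growth descriptors: RGR, exponential fits, curves, survival, quartiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from phenowell.growth import (GrowthSeries, fit_exponential, group_curve,
                              interval_percent_increase, quartile_summary,
                              rgr, survival_curve, survival_rate)
from phenowell.synth import GrowthModel, simulate_growth


def _series(areas, times=None, treatment="Control"):
    times = np.arange(len(areas)) if times is None else times
    return GrowthSeries("p", treatment, np.asarray(times, float),
                        np.asarray(areas, float))


class TestRGR:
    def test_constant_series_is_zero(self):
        r = rgr(_series([100] * 5))
        np.testing.assert_allclose(r.values, 0.0)

    def test_exponential_closed_form(self):
        t = np.arange(10)
        r = rgr(_series(50 * np.exp(0.5 * t), t))
        np.testing.assert_allclose(r.values, 0.5, rtol=1e-12)
        np.testing.assert_allclose(r.midpoints, t[:-1] + 0.5)

    def test_doubling_daily_is_ln2(self):
        r = rgr(_series([100, 200, 400, 800]))
        np.testing.assert_allclose(r.values, math.log(2), rtol=1e-12)

    def test_zero_area_gives_nan_not_exception(self):
        r = rgr(_series([100, 200, 0, 0, 50]))
        assert np.isfinite(r.values[0])
        assert np.isnan(r.values[1:4]).all()
        assert len(r.values) == 4


class TestFitExponential:
    def test_exact_exponential_recovered(self):
        t = np.arange(9, dtype=float)
        fit = fit_exponential(_series(120 * np.exp(0.37 * t), t))
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert fit.rate == pytest.approx(0.37, abs=1e-12)
        assert fit.a0 == pytest.approx(120, rel=1e-10)
        assert fit.p_value < 1e-6

    def test_matches_brute_force_log_least_squares(self, rng):
        """Independent oracle: grid search over (ln A0, r) minimising squared
        log-residuals converges to the same optimum as the OLS fit."""
        t = np.arange(8, dtype=float)
        areas = 200 * np.exp(0.4 * t) * np.exp(rng.normal(0, 0.15, len(t)))
        fit = fit_exponential(_series(areas, t))
        best = None
        for la0 in np.linspace(math.log(100), math.log(400), 601):
            for r in np.linspace(0.2, 0.6, 401):
                sse = float(np.sum((np.log(areas) - (la0 + r * t)) ** 2))
                if best is None or sse < best[0]:
                    best = (sse, la0, r)
        assert fit.rate == pytest.approx(best[2], abs=2e-3)
        assert math.log(fit.a0) == pytest.approx(best[1], abs=2e-3)

    def test_noisy_parameter_recovery(self):
        """Mean estimated rate over 200 noisy exponentials within 2 SE."""
        model = GrowthModel(noise_sd=0.1, rng_seed=5,
                            treatment_effects={"X": 1.0},
                            mortality_hazard={"X": 0.0}, baseline_rgr=0.4)
        rates = [fit_exponential(s).rate
                 for s in simulate_growth(model, 200, "X", 9)]
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(np.mean(rates) - 0.4) < 2 * se + 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3"):
            fit_exponential(_series([0, 0, 10, 20]))


class TestGroupCurve:
    def test_identical_series_zero_se(self):
        curve = group_curve([_series([10, 20, 30])] * 4)
        np.testing.assert_allclose(curve["se"], 0.0)
        np.testing.assert_allclose(curve["mean"], [10, 20, 30])

    def test_hand_computed_se(self):
        curve = group_curve([_series([100]), _series([300])])
        assert curve["mean"].iloc[0] == 200
        assert curve["se"].iloc[0] == pytest.approx(100.0)  # sd/sqrt(2)

    def test_permutation_invariance(self, rng):
        ss = [_series(rng.uniform(1, 100, 5)) for _ in range(6)]
        a = group_curve(ss)
        b = group_curve(ss[::-1])
        np.testing.assert_allclose(a["mean"], b["mean"])
        np.testing.assert_allclose(a["se"], b["se"])

    def test_empty_and_mismatched(self):
        with pytest.raises(ValueError):
            group_curve([])
        with pytest.raises(ValueError, match="time grid"):
            group_curve([_series([1, 2]), _series([1, 2, 3])])


class TestIntervalIncrease:
    def test_definition(self):
        pct = interval_percent_increase(_series([100, 102]), 1)
        np.testing.assert_allclose(pct, [2.0])

    def test_exponential_two_hour_window(self):
        """r = 0.24/day over 2 h gives 100*(e^(0.24*2/24)-1) ~ 2.02%."""
        t = np.arange(0, 1.01, 2 / 24)
        a = 1000 * np.exp(0.24 * t)
        pct = interval_percent_increase(_series(a, t), 2 / 24)
        np.testing.assert_allclose(pct, 100 * (math.exp(0.24 * 2 / 24) - 1),
                                   rtol=1e-9)

    def test_constant_series(self):
        pct = interval_percent_increase(_series([5, 5, 5, 5]), 2)
        np.testing.assert_allclose(pct, 0.0)

    def test_window_too_long(self):
        with pytest.raises(ValueError):
            interval_percent_increase(_series([1, 2]), 5)


class TestSurvival:
    def test_all_alive(self):
        assert survival_rate([_series([5, 10, 20])] * 3, 2) == 100.0

    def test_half_dead(self):
        alive = [_series([10, 20, 30])] * 12
        dead = [_series([10, 0, 0])] * 12
        assert survival_rate(alive + dead, 2) == 50.0

    def test_death_is_absorbing(self):
        # area recovers above threshold later, but the plant stays dead
        zombie = _series([10, 0, 50])
        assert survival_rate([zombie], 2) == 0.0

    def test_order_invariance(self, rng):
        ss = [_series(rng.choice([0, 5, 10], 4)) for _ in range(10)]
        perm = list(rng.permutation(10))
        for d in range(4):
            assert survival_rate(ss, d) == survival_rate([ss[i] for i in perm], d)

    def test_curve_monotone_on_simulated_mortality(self):
        model = GrowthModel(rng_seed=3)
        ss = simulate_growth(model, 100, "NaCl150", 9)
        surv = survival_curve(ss)["survival"].to_numpy()
        assert np.all(np.diff(surv) <= 0)

    def test_out_of_range_day(self):
        with pytest.raises(ValueError):
            survival_rate([_series([1, 2])], 5)


class TestQuartileSummary:
    def test_five_point_convention(self):
        q = quartile_summary([1, 2, 3, 4, 5])
        assert (q.q1, q.median, q.q3) == (2, 3, 4)
        assert (q.minimum, q.maximum, q.n) == (1, 5, 5)

    def test_all_zeros(self):
        q = quartile_summary([0, 0, 0, 0])
        assert (q.q1, q.median, q.q3, q.minimum, q.maximum, q.se) == (0,) * 6

    def test_matches_sorted_array_oracle(self, rng):
        """Brute-force oracle: linear interpolation between order statistics."""
        for _ in range(20):
            x = rng.uniform(0, 1000, int(rng.integers(2, 40)))
            q = quartile_summary(x)
            s = np.sort(x)

            def interp(p):
                pos = p * (len(s) - 1)
                lo, frac = int(math.floor(pos)), pos % 1
                return s[lo] + frac * (s[min(lo + 1, len(s) - 1)] - s[lo])

            assert q.q1 == pytest.approx(interp(0.25), rel=1e-12)
            assert q.median == pytest.approx(interp(0.5), rel=1e-12)
            assert q.q3 == pytest.approx(interp(0.75), rel=1e-12)
            assert q.se == pytest.approx(np.std(x, ddof=1) / math.sqrt(len(x)))

    @given(hst.lists(hst.floats(0, 1e6, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_ordering_invariant(self, xs):
        q = quartile_summary(xs)
        assert q.minimum <= q.q1 <= q.median <= q.q3 <= q.maximum


def test_rgr_and_fit_agree_on_noiseless_exponentials():
    """Mean interval RGR equals the fitted rate when growth is exactly
    exponential (both estimate the same r)."""
    model = GrowthModel(noise_sd=0.0, rng_seed=0,
                        treatment_effects={"X": 0.8},
                        mortality_hazard={"X": 0.0}, baseline_rgr=0.5)
    for s in simulate_growth(model, 5, "X", 9):
        r_mean = float(np.nanmean(rgr(s).values))
        r_fit = fit_exponential(s).rate
        assert r_mean == pytest.approx(r_fit, abs=1e-10)
        assert r_fit == pytest.approx(0.4, abs=1e-12)


def test_series_validation():
    with pytest.raises(ValueError):
        _series([1, 2, 3], times=[0, 0, 1])
    with pytest.raises(ValueError):
        _series([-1, 2])
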