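import cmath

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, strategies as st
from scipy import stats as sps

from conftest import planted_series
from seasmort import circular
from seasmort.errors import SchemaError, UndefinedCircularMeanError


def brute_force_mean_month(months, weights):
    """Independent oracle: explicit complex-sum loop with cmath."""
    z = 0j
    for m, w in zip(months, weights):
        z += w * cmath.exp(1j * 2 * cmath.pi * (m - 1) / 12)
    theta = cmath.phase(z) % (2 * cmath.pi)
    return 1 + 12 * theta / (2 * cmath.pi)


def _resultant_defined(months, weights):
    z = sum(w * cmath.exp(1j * 2 * cmath.pi * (m - 1) / 12)
            for m, w in zip(months, weights))
    return abs(z) / sum(weights) > 1e-6


class TestAngles:
    @pytest.mark.parametrize("month,theta", [
        (1, 0.0), (4, np.pi / 2), (7, np.pi), (10, 3 * np.pi / 2),
    ])
    def test_month_to_angle(self, month, theta):
        assert circular.month_to_angle(month) == pytest.approx(theta)

    def test_round_trip_december(self):
        theta = circular.month_to_angle(12)
        assert theta == pytest.approx(11 * np.pi / 6)
        assert circular.angle_to_month(theta) == pytest.approx(12.0)

    def test_out_of_range(self):
        with pytest.raises(SchemaError):
            circular.month_to_angle(13)
        with pytest.raises(SchemaError):
            circular.month_to_angle(0.5)


class TestWeightedCircularMean:
    def test_all_weight_on_january(self):
        cm = circular.weighted_circular_mean([1], [5.0])
        assert cm.month == pytest.approx(1.0)
        assert cm.resultant_length == pytest.approx(1.0)
        assert cm.circular_variance == pytest.approx(0.0)

    def test_december_february_wraps_to_january(self):
        cm = circular.weighted_circular_mean([12, 2], [1.0, 1.0])
        assert cm.month == pytest.approx(1.0)

    def test_january_two_february_one(self):
        cm = circular.weighted_circular_mean([1, 2], [2.0, 1.0])
        assert cm.month == pytest.approx(
            brute_force_mean_month([1, 2], [2.0, 1.0]))
        assert cm.month == pytest.approx(1.33, abs=0.01)

    def test_uniform_weights_undefined(self):
        with pytest.raises(UndefinedCircularMeanError):
            circular.weighted_circular_mean(list(range(1, 13)), [1.0] * 12)

    @given(st.lists(
        st.tuples(st.integers(1, 12), st.floats(0.01, 100.0)),
        min_size=1, max_size=12,
    ))
    def test_matches_brute_force_oracle(self, pairs):
        months = [m for m, _ in pairs]
        weights = [w for _, w in pairs]
        assume(_resultant_defined(months, weights))
        cm = circular.weighted_circular_mean(months, weights)
        expected = brute_force_mean_month(months, weights)
        assert abs(circular.month_difference(cm.month, expected)) < 1e-9

    @given(
        st.lists(st.tuples(st.integers(1, 12), st.integers(1, 5)),
                 min_size=1, max_size=8),
    )
    def test_integer_weights_match_scipy_circmean(self, pairs):
        # independent route: expand weights into repeated observations and use
        # scipy's (unweighted) circular mean
        months = [m for m, _ in pairs]
        weights = [w for _, w in pairs]
        assume(_resultant_defined(months, weights))
        cm = circular.weighted_circular_mean(months, weights)
        expanded = np.repeat(circular.month_to_angle(np.array(months, float)),
                             weights)
        expected = sps.circmean(expanded, high=2 * np.pi, low=0)
        diff = (cm.theta_bar - expected + np.pi) % (2 * np.pi) - np.pi
        assert abs(diff) < 1e-9

    @given(
        st.lists(st.tuples(st.integers(1, 12), st.floats(0.5, 10.0)),
                 min_size=2, max_size=12),
        st.integers(1, 11),
    )
    def test_rotation_equivariance(self, pairs, k):
        months = np.array([m for m, _ in pairs])
        weights = [w for _, w in pairs]
        assume(_resultant_defined(months, weights))
        base = circular.weighted_circular_mean(months, weights)
        shifted = circular.weighted_circular_mean(
            (months - 1 + k) % 12 + 1, weights)
        assert abs(circular.month_difference(shifted.month,
                                             base.month + k)) < 1e-9

    @given(
        st.lists(st.tuples(st.integers(1, 12), st.floats(0.5, 10.0)),
                 min_size=2, max_size=12),
        st.floats(0.1, 1000.0),
    )
    def test_scale_invariance(self, pairs, c):
        months = [m for m, _ in pairs]
        weights = np.array([w for _, w in pairs])
        assume(_resultant_defined(months, weights))
        a = circular.weighted_circular_mean(months, weights)
        b = circular.weighted_circular_mean(months, c * weights)
        assert a.theta_bar == pytest.approx(b.theta_bar)
        assert a.resultant_length == pytest.approx(b.resultant_length)


class TestCentreOfGravity:
    def test_single_active_month(self, monthly_index):
        idx = monthly_index(2000, 2004)
        values = np.where(idx.month == 6, 8.0, 0.0)
        cm = circular.centre_of_gravity(pd.Series(values, index=idx))
        assert cm.month == pytest.approx(6.0)

    def test_flat_series_undefined(self, monthly_index):
        idx = monthly_index(2000, 2004)
        with pytest.raises(UndefinedCircularMeanError):
            circular.centre_of_gravity(pd.Series(10.0, index=idx))

    def test_planted_january_peak_recovered(self):
        series, _, _ = planted_series(baseline=2000.0, amplitude=0.3,
                                      phase=1.0, seed=17)
        cm = circular.centre_of_gravity(series)
        assert abs(circular.month_difference(cm.month, 1.0)) < 0.5

    def test_per_year_average_variant_agrees_on_stable_signal(self):
        series, _, _ = planted_series(baseline=5000.0, amplitude=0.3,
                                      phase=1.0, seed=19)
        pooled = circular.centre_of_gravity(series)
        yearly = circular.centre_of_gravity(series, per_year_average=True)
        assert abs(circular.month_difference(pooled.month, yearly.month)) < 0.25


class TestNegativeCentreOfGravity:
    def test_single_minimum_month(self, monthly_index):
        idx = monthly_index(2000, 2002)
        values = np.where(idx.month == 7, 2.0, 10.0)
        cm = circular.negative_centre_of_gravity(pd.Series(values, index=idx))
        assert cm.month == pytest.approx(7.0)

    def test_constant_series_undefined(self, monthly_index):
        idx = monthly_index(2000, 2002)
        with pytest.raises(UndefinedCircularMeanError):
            circular.negative_centre_of_gravity(pd.Series(3.0, index=idx))

    def test_planted_january_peak_gives_july_minimum(self):
        series, _, _ = planted_series(baseline=2000.0, amplitude=0.3,
                                      phase=1.0, seed=23)
        cm = circular.negative_centre_of_gravity(series)
        assert abs(circular.month_difference(cm.month, 7.0)) < 0.5

    def test_complementarity_on_pure_cosine(self, cosine_rate_series):
        series = cosine_rate_series(amplitude=0.3, phase=1.0)
        cog = circular.centre_of_gravity(series)
        neg = circular.negative_centre_of_gravity(series)
        assert abs(abs(circular.month_difference(cog.month, neg.month)) - 6) < 0.1


class TestBootstrap:
    def test_point_mass_gives_zero_width_ci(self, monthly_index):
        idx = monthly_index(2000, 2009)
        values = np.where(idx.month == 2, 5.0, 0.0)
        ci = circular.bootstrap_ci(pd.Series(values, index=idx), "cog",
                                   n=200, seed=0)
        assert ci.width == pytest.approx(0.0)
        assert ci.lo == pytest.approx(2.0) and ci.hi == pytest.approx(2.0)

    def test_ci_contains_point_estimate(self):
        series, _, _ = planted_series(baseline=500.0, amplitude=0.2,
                                      phase=1.0, seed=31)
        point = circular.centre_of_gravity(series)
        ci = circular.bootstrap_ci(series, "cog", n=500, seed=1)
        assert ci.contains(point.month)

    def test_seed_reproducibility(self):
        series, _, _ = planted_series(baseline=500.0, amplitude=0.2, seed=33)
        a = circular.bootstrap_ci(series, "negative_cog", n=300, seed=9)
        b = circular.bootstrap_ci(series, "negative_cog", n=300, seed=9)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_full_analysis_bundle(self):
        series, _, _ = planted_series(baseline=500.0, amplitude=0.2,
                                      phase=1.0, seed=35)
        res = circular.cog_analysis(series, n_bootstrap=300, seed=2)
        assert res.ci95_max.contains(res.max_timing.month)
        assert res.ci95_min.contains(res.min_timing.month)
        assert res.n_bootstrap == 300
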