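import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from seasmort import trend
from seasmort.errors import SchemaError


def year_series(values_by_year):
    """Build a monthly series from {year: 12 values}."""
    years = sorted(values_by_year)
    idx = pd.period_range(f"{years[0]}-01", f"{years[-1]}-12", freq="M")
    values = np.concatenate([np.asarray(values_by_year[y], float)
                             for y in years])
    return pd.Series(values, index=idx)


class TestYearlyPercentDifference:
    def test_simple_max_min(self):
        vals = [80.0] * 12
        vals[0], vals[6] = 120.0, 80.0
        s = year_series({2000: vals})
        (d,) = trend.yearly_percent_difference(s, s)
        assert d.percent_diff == pytest.approx(50.0)
        assert d.max_month == 1 and d.min_month == 2  # first 80 is February

    def test_constant_year_ties_to_january(self):
        s = year_series({2000: [10.0] * 12})
        (d,) = trend.yearly_percent_difference(s, s)
        assert d.percent_diff == pytest.approx(0.0)
        assert d.max_month == 1 and d.min_month == 1

    def test_tied_maximum_earliest_month(self):
        vals = [50.0] * 12
        vals[2] = vals[8] = 90.0
        vals[5] = 30.0
        s = year_series({2000: vals})
        (d,) = trend.yearly_percent_difference(s, s)
        assert d.max_month == 3
        assert d.percent_diff == pytest.approx(200.0)

    def test_zero_minimum_rate_flagged_unusable(self):
        vals = list(np.linspace(10, 120, 12))
        vals[4] = 0.0
        s = year_series({2000: vals})
        (d,) = trend.yearly_percent_difference(s, s)
        assert d.percent_diff is None and not d.usable

    def test_max_denominator_variant(self):
        vals = [80.0] * 12
        vals[0] = 120.0
        s = year_series({2000: vals})
        (d,) = trend.yearly_percent_difference(s, s, denominator="max")
        assert d.percent_diff == pytest.approx(100 * 40 / 120)

    def test_incomplete_year_rejected(self):
        idx = pd.period_range("2000-01", "2000-11", freq="M")
        s = pd.Series(1.0, index=idx)
        with pytest.raises(SchemaError):
            trend.yearly_percent_difference(s, s)

    @given(st.floats(0.1, 50.0))
    def test_scale_invariance_within_year(self, c):
        rng = np.random.default_rng(7)
        vals = rng.uniform(10, 100, 12)
        base = year_series({2000: vals})
        scaled = year_series({2000: vals * c})
        (a,) = trend.yearly_percent_difference(base, base)
        (b,) = trend.yearly_percent_difference(scaled, scaled)
        assert b.percent_diff == pytest.approx(a.percent_diff)


class TestPoissonSE:
    def _diff(self, d_max, d_min):
        return trend.SeasonalDifference(
            year=2000, max_month=1, min_month=7, r_max=float(d_max),
            r_min=float(d_min), d_max=float(d_max), d_min=float(d_min),
            percent_diff=(100.0 * (d_max - d_min) / d_min
                          if d_min > 0 else None),
        )

    def test_closed_form_200_100(self):
        se = trend.poisson_se(self._diff(200, 100))
        assert se == pytest.approx(200 * math.sqrt(0.015))
        assert se == pytest.approx(24.4949, abs=1e-4)

    def test_quadrupling_counts_halves_se(self):
        assert trend.poisson_se(self._diff(800, 400)) == pytest.approx(
            trend.poisson_se(self._diff(200, 100)) / 2)

    def test_zero_count_infinite_variance(self):
        assert math.isinf(trend.poisson_se(self._diff(200, 0)))

    def test_parametric_bootstrap_oracle(self):
        # independent oracle: simulate Poisson month pairs (equal populations
        # and month lengths), take the SD of the percent difference
        rng = np.random.default_rng(2024)
        d_max = rng.poisson(200, size=400_000)
        d_min = rng.poisson(100, size=400_000)
        keep = d_min > 0
        pct = 100.0 * (d_max[keep] - d_min[keep]) / d_min[keep]
        mc_sd = pct.std()
        se = trend.poisson_se(self._diff(200, 100))
        assert se == pytest.approx(mc_sd, rel=0.05)


class TestWeightedTrend:
    def _diffs(self, years, pcts, ses):
        out = []
        for y, p, s in zip(years, pcts, ses):
            d = trend.SeasonalDifference(
                year=int(y), max_month=1, min_month=7, r_max=1.0, r_min=1.0,
                d_max=100.0, d_min=100.0, percent_diff=float(p), se=float(s))
            out.append(d)
        return out

    def test_exact_line_equal_weights(self):
        years = np.arange(1980, 2017)
        pcts = 40.0 - 0.5 * (years - 1980)
        fit = trend.fit_weighted_trend(self._diffs(years, pcts, [2.0] * 37))
        assert fit.slope == pytest.approx(-0.5)
        assert fit.fitted_start == pytest.approx(40.0)
        assert fit.fitted_end == pytest.approx(22.0)
        assert fit.change == pytest.approx(-18.0)

    def test_change_equals_slope_times_span(self):
        rng = np.random.default_rng(5)
        years = np.arange(1980, 2017)
        pcts = 30 + rng.normal(0, 3, 37)
        fit = trend.fit_weighted_trend(
            self._diffs(years, pcts, rng.uniform(1, 4, 37)))
        assert fit.change == pytest.approx(fit.slope * 36)

    def test_equal_weights_reproduce_ols(self):
        rng = np.random.default_rng(6)
        years = np.arange(1990, 2011)
        pcts = 20 + 0.3 * (years - 1990) + rng.normal(0, 2, years.size)
        fit = trend.fit_weighted_trend(
            self._diffs(years, pcts, [3.0] * years.size))
        slope_ols, intercept_ols = np.polyfit(years.astype(float), pcts, 1)
        assert fit.slope == pytest.approx(slope_ols)
        assert fit.intercept == pytest.approx(intercept_ols)

    def test_unusable_years_excluded(self):
        years = np.arange(2000, 2010)
        pcts = 10.0 + 0.0 * years
        diffs = self._diffs(years, pcts, [1.0] * 10)
        diffs[3].percent_diff = None
        diffs[3].se = None
        fit = trend.fit_weighted_trend(diffs)
        assert fit.n_years_used == 9
        # fitted endpoints still evaluated at the window's first/last year
        assert fit.start_year == 2000 and fit.end_year == 2009

    def test_too_few_years(self):
        with pytest.raises(SchemaError):
            trend.fit_weighted_trend(self._diffs([2000, 2001], [1, 2], [1, 1]))


class TestPeakMinusTroughTemperature:
    CLIM = {1: 0.0, 7: 25.0, 2: 5.0}

    def test_winter_peak_summer_trough(self):
        delta = trend.peak_minus_trough_temperature(self.CLIM, 1, 7)
        assert delta == pytest.approx(-25.0)

    def test_same_month_is_zero(self):
        assert trend.peak_minus_trough_temperature(self.CLIM, 2, 2) == 0.0

    def test_missing_month_raises(self):
        with pytest.raises(SchemaError):
            trend.peak_minus_trough_temperature(self.CLIM, 3, 7)
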