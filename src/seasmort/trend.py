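"""Peak-vs-trough percent mortality differences and their long-run trend.

For each calendar year the maximum- and minimum-rate months are identified
empirically (after month-length correction), without assuming that any fixed
set of months is the seasonal peak.  The percent difference
``100 * (r_max - r_min) / r_min`` gets a delta-method standard error that
treats the two months' death counts as independent Poisson variables, and the
per-year differences are combined into a linear trend by inverse-variance
weighted least squares.  The fitted line yields the change in seasonal
amplitude between the first and last year of the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SchemaError
from .rates import as_series

logger = logging.getLogger(__name__)


@dataclass
class SeasonalDifference:
    """One year's peak-vs-trough contrast.

    ``se`` is None until :func:`poisson_se` fills it; ``percent_diff`` is
    None when the minimum-month rate is zero (the year is then excluded from
    trend fitting).
    """

    year: int
    max_month: int
    min_month: int
    r_max: float
    r_min: float
    d_max: float
    d_min: float
    percent_diff: float | None
    se: float | None = None

    @property
    def usable(self) -> bool:
        return (self.percent_diff is not None and self.se is not None
                and math.isfinite(self.se) and self.se > 0)


def poisson_se(diff: SeasonalDifference) -> float:
    """Delta-method SE of the percent difference under independent Poisson
    counts in the two months: ``100 * (r_max/r_min) * sqrt(1/d_max + 1/d_min)``.

    Returns ``inf`` (an infinite-variance signal) when either count is zero.
    """
    if diff.d_max <= 0 or diff.d_min <= 0 or diff.r_min <= 0:
        return math.inf
    return 100.0 * (diff.r_max / diff.r_min) * math.sqrt(
        1.0 / diff.d_max + 1.0 / diff.d_min
    )


def yearly_percent_difference(rates, counts=None,
                              denominator: str = "min") -> list[SeasonalDifference]:
    """Per-year percent difference between the maximum- and minimum-rate months.

    ``rates`` and ``counts`` are aligned monthly series over full calendar
    years.  ``counts`` are the raw (uncorrected) death counts of each month,
    used only for the Poisson SE: the month-length correction is a
    deterministic rescaling, so the Poisson variation lives in the raw count.
    Ties for the extreme months break to the earliest month.  ``denominator``
    selects the reference rate: ``"min"`` (default) or ``"max"``.
    """
    if denominator not in ("min", "max"):
        raise SchemaError("denominator must be 'min' or 'max'")
    r = as_series(rates)
    c = as_series(counts) if counts is not None else None
    if c is not None and not r.index.equals(c.index):
        raise SchemaError("rate and count indices do not align")
    if not isinstance(r.index, pd.PeriodIndex):
        raise SchemaError("expected a monthly PeriodIndex series")

    out = []
    for year, grp in r.groupby(r.index.year):
        if len(grp) != 12:
            raise SchemaError(f"year {year} has {len(grp)} months; need 12")
        values = grp.to_numpy(dtype=float)
        i_max = int(np.argmax(values))  # argmax/argmin take the first = earliest
        i_min = int(np.argmin(values))
        r_max, r_min = float(values[i_max]), float(values[i_min])
        if c is not None:
            cy = c[c.index.year == year].to_numpy(dtype=float)
            d_max, d_min = float(cy[i_max]), float(cy[i_min])
        else:
            d_max, d_min = r_max, r_min
        denom = r_min if denominator == "min" else r_max
        if denom <= 0:
            logger.warning("year %d has a zero %s-month rate; percent "
                           "difference undefined", year, denominator)
            pct = None
        else:
            pct = 100.0 * (r_max - r_min) / denom
        d = SeasonalDifference(
            year=int(year), max_month=i_max + 1, min_month=i_min + 1,
            r_max=r_max, r_min=r_min, d_max=d_max, d_min=d_min,
            percent_diff=pct,
        )
        d.se = poisson_se(d)
        out.append(d)
    return out


@dataclass
class TrendFit:
    """Inverse-variance weighted linear trend of the seasonal difference."""

    slope: float          # percentage points per year
    slope_se: float
    p_value: float        # two-sided, normal approximation
    intercept: float
    fitted_start: float
    fitted_end: float
    change: float         # fitted_end - fitted_start
    start_year: int
    end_year: int
    n_years_used: int


def fit_weighted_trend(diffs: list[SeasonalDifference]) -> TrendFit:
    """Weighted least squares of percent difference on year, weights 1/se^2.

    Years with undefined difference or infinite variance are excluded.  The
    fitted endpoints are evaluated at the first and last year present in
    ``diffs`` (whether or not those years were usable).
    """
    if not diffs:
        raise SchemaError("no seasonal differences to fit")
    usable = [d for d in diffs if d.usable]
    if len(usable) < 3:
        raise SchemaError(f"need >= 3 usable years, have {len(usable)}")
    years = np.array([d.year for d in usable], dtype=float)
    y = np.array([d.percent_diff for d in usable], dtype=float)
    w = np.array([1.0 / d.se ** 2 for d in usable])
    if not np.isfinite(w).all() or (w <= 0).all():
        raise SchemaError("no positive finite weights")
    X = sm.add_constant(years)
    fit = sm.WLS(y, X, weights=w).fit()
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    # the weights are known Poisson variances, so the slope SE comes from the
    # fixed-scale (inverse-variance) covariance, not a residual-estimated scale
    slope_se = float(np.sqrt(np.asarray(fit.cov_params(scale=1.0))[1, 1]))
    p = float(2.0 * stats.norm.sf(abs(slope / slope_se)))
    y0 = int(min(d.year for d in diffs))
    y1 = int(max(d.year for d in diffs))
    f0 = intercept + slope * y0
    f1 = intercept + slope * y1
    return TrendFit(
        slope=slope, slope_se=slope_se, p_value=p, intercept=intercept,
        fitted_start=f0, fitted_end=f1, change=f1 - f0,
        start_year=y0, end_year=y1, n_years_used=len(usable),
    )


def peak_minus_trough_temperature(region_monthly_temp, max_month: int,
                                  min_month: int) -> float:
    """Temperature (degC) of the maximum-mortality month minus that of the
    minimum-mortality month, from a region's monthly climatology.

    ``region_monthly_temp`` maps calendar month (1..12) to temperature; the
    months are the nearest-integer months of a timing analysis.
    """
    try:
        t_max = float(region_monthly_temp[int(max_month)])
        t_min = float(region_monthly_temp[int(min_month)])
    except KeyError as exc:
        raise SchemaError(f"missing monthly temperature for month {exc}") from exc
    return t_max - t_min


def trend_table(diffs: list[SeasonalDifference]) -> pd.DataFrame:
    """Yearly table of seasonal differences (machine-readable output)."""
    return pd.DataFrame([{
        "year": d.year, "max_month": d.max_month, "min_month": d.min_month,
        "rate_max": d.r_max, "rate_min": d.r_min,
        "percent_diff": d.percent_diff, "se": d.se, "usable": d.usable,
    } for d in diffs])
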