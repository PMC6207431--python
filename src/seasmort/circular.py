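"""Circular-statistics timing of maximum and minimum mortality.

Calendar months are placed at 12 equally spaced angles on the unit circle, so
December neighbours January.  The centre of gravity of mortality is the
weighted circular mean of months with each (year, month) cell weighted by its
death rate; it estimates the timing of maximum mortality.  The negative
centre of gravity weights each month by the shortfall of its rate below that
year's maximum, and estimates the timing of minimum mortality.

The mean direction is the argument of the complex weighted sum
``theta_bar = arg sum_j w_j exp(i theta_j)``; the normalised resultant length
``R in [0, 1]`` measures concentration and ``1 - R`` is the circular
variance.  A zero resultant (e.g. perfectly uniform weights) leaves the mean
undefined and raises :class:`UndefinedCircularMeanError` — it never
silently becomes a number.

Confidence intervals are percentile bootstrap intervals on shortest-arc
angular deviations from the point estimate, resampling calendar years with
replacement (a block bootstrap that respects within-year dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import StratumKey
from .errors import (
    BootstrapFailureError,
    SchemaError,
    UndefinedCircularMeanError,
)
from .rates import as_series

_RESULTANT_TOL = 1e-12


def month_to_angle(month):
    """Angle (radians) of a calendar month: theta = 2*pi*(month - 1)/12."""
    m = np.asarray(month, dtype=float)
    if np.any((m < 1) | (m > 12)):
        raise SchemaError("month out of range [1, 12]")
    return 2.0 * np.pi * (m - 1.0) / 12.0


def angle_to_month(theta):
    """Continuous month in [1, 13) corresponding to an angle."""
    t = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
    return 1.0 + 12.0 * t / (2.0 * np.pi)


def month_difference(a, b):
    """Signed shortest-arc difference a - b in months, in (-6, 6]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 12.0)
    return np.where(d > 6.0, d - 12.0, d)


@dataclass(frozen=True)
class CircularMean:
    theta_bar: float
    month: float              # continuous month in [1, 13)
    resultant_length: float   # normalised, in [0, 1]
    circular_variance: float  # 1 - resultant_length

    @property
    def nearest_month(self) -> int:
        """Nearest integer calendar month in 1..12."""
        return int(np.mod(np.rint(self.month) - 1, 12) + 1)


def weighted_circular_mean(months, weights) -> CircularMean:
    """Mean direction of months under non-negative weights.

    Raises :class:`UndefinedCircularMeanError` when the resultant vector has
    (numerically) zero length.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w < 0):
        raise SchemaError("weights must be non-negative and non-empty")
    total = w.sum()
    if total <= 0:
        raise UndefinedCircularMeanError("all weights are zero")
    z = np.sum(w * np.exp(1j * month_to_angle(months)))
    r = np.abs(z) / total
    if r < _RESULTANT_TOL:
        raise UndefinedCircularMeanError("zero resultant length")
    theta = float(np.mod(np.angle(z), 2.0 * np.pi))
    return CircularMean(theta, float(angle_to_month(theta)), float(r),
                        float(1.0 - r))


def _series_table(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s = as_series(series)
    if not isinstance(s.index, pd.PeriodIndex):
        raise SchemaError("expected a monthly PeriodIndex series")
    values = s.to_numpy(dtype=float)
    if np.any(values < 0):
        raise SchemaError("negative rates")
    return s.index.year.to_numpy(), s.index.month.to_numpy(), values


def _cog_weights(series, kind: str) -> tuple[np.ndarray, np.ndarray]:
    years, months, values = _series_table(series)
    if kind == "cog":
        return months, values
    if kind == "negative_cog":
        # weight = year's maximum rate minus the month's rate
        df = pd.DataFrame({"year": years, "value": values})
        year_max = df.groupby("year")["value"].transform("max").to_numpy()
        return months, year_max - values
    raise SchemaError(f"unknown statistic {kind!r}")


def _pooled_or_yearly(series, kind: str, per_year_average: bool) -> CircularMean:
    if not per_year_average:
        months, weights = _cog_weights(series, kind)
        return weighted_circular_mean(months, weights)
    # variant: one unit vector per year at that year's mean direction,
    # averaged with equal year weights
    zsum, wsum = _year_resultants(series, kind)
    ok = (wsum > 0) & (np.abs(zsum) > _RESULTANT_TOL)
    if not ok.any():
        raise UndefinedCircularMeanError("no year has a defined mean")
    unit = zsum[ok] / np.abs(zsum[ok])
    z = unit.sum()
    r = np.abs(z) / ok.sum()
    if r < _RESULTANT_TOL:
        raise UndefinedCircularMeanError("zero resultant length")
    theta = float(np.mod(np.angle(z), 2.0 * np.pi))
    return CircularMean(theta, float(angle_to_month(theta)), float(r),
                        float(1.0 - r))


def centre_of_gravity(series, per_year_average: bool = False) -> CircularMean:
    """Timing of maximum mortality: months weighted by their death rates.

    By default every (year, month) cell of the window is one weighted
    observation (pooling); ``per_year_average`` instead averages per-year
    mean directions with equal year weights.
    """
    return _pooled_or_yearly(series, "cog", per_year_average)


def negative_centre_of_gravity(series, per_year_average: bool = False) -> CircularMean:
    """Timing of minimum mortality: months weighted by the within-year
    shortfall below the year's maximum rate."""
    return _pooled_or_yearly(series, "negative_cog", per_year_average)


@dataclass(frozen=True)
class CircularInterval:
    """A circular 95% interval around a point estimate, in month units."""

    lo: float
    hi: float
    point: float

    def contains(self, month: float) -> bool:
        d = month_difference(month, self.point)
        return (month_difference(self.lo, self.point)
                <= d <= month_difference(self.hi, self.point))

    @property
    def width(self) -> float:
        return float(month_difference(self.hi, self.point)
                     - month_difference(self.lo, self.point))


def _year_resultants(series, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-year complex resultants and weight totals.

    Both statistics assign each cell a weight that depends only on its own
    year, so a year-block bootstrap replicate's resultant is a sum of
    per-year contributions.
    """
    months, weights = _cog_weights(series, kind)
    years = as_series(series).index.year.to_numpy()
    z = weights * np.exp(1j * month_to_angle(months))
    uniq = np.unique(years)
    zsum = np.array([z[years == y].sum() for y in uniq])
    wsum = np.array([weights[years == y].sum() for y in uniq])
    return zsum, wsum


def bootstrap_ci(series, statistic: str = "cog", n: int = 1000,
                 seed=None, level: float = 0.95) -> CircularInterval:
    """Percentile bootstrap interval for a circular timing statistic.

    Calendar years are resampled with replacement; the interval is formed on
    shortest-arc deviations (months) of replicate estimates from the point
    estimate.  Raises :class:`BootstrapFailureError` if the statistic is
    undefined in more than half of the replicates.
    """
    if n < 1:
        raise SchemaError("n must be >= 1")
    months, weights = _cog_weights(series, statistic)
    point = weighted_circular_mean(months, weights)
    zsum, wsum = _year_resultants(series, statistic)
    n_years = zsum.size
    if n_years < 2:
        raise SchemaError("need at least 2 years to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_years, size=(n, n_years))
    z = zsum[idx].sum(axis=1)
    w = wsum[idx].sum(axis=1)
    ok = (w > 0) & (np.abs(z) / np.maximum(w, _RESULTANT_TOL) >= _RESULTANT_TOL)
    if ok.sum() < n / 2:
        raise BootstrapFailureError(
            f"statistic undefined in {n - int(ok.sum())} of {n} replicates"
        )
    rep_months = angle_to_month(np.angle(z[ok]))
    dev = month_difference(rep_months, point.month)
    alpha = (1.0 - level) / 2.0
    lo_dev, hi_dev = np.quantile(dev, [alpha, 1.0 - alpha])
    lo = float(np.mod(point.month + lo_dev - 1.0, 12.0) + 1.0)
    hi = float(np.mod(point.month + hi_dev - 1.0, 12.0) + 1.0)
    return CircularInterval(lo=lo, hi=hi, point=point.month)


@dataclass
class CoGResult:
    """Timing of maximum and minimum mortality for one stratum, with CIs."""

    stratum: StratumKey | None
    max_timing: CircularMean
    min_timing: CircularMean
    ci95_max: CircularInterval
    ci95_min: CircularInterval
    n_bootstrap: int


def cog_analysis(series, stratum: StratumKey | None = None,
                 n_bootstrap: int = 1000, seed=None) -> CoGResult:
    """Full timing analysis of one monthly rate series."""
    rng = np.random.default_rng(seed)
    s_max, s_min = rng.integers(0, 2**31, size=2)
    return CoGResult(
        stratum=stratum,
        max_timing=centre_of_gravity(series),
        min_timing=negative_centre_of_gravity(series),
        ci95_max=bootstrap_ci(series, "cog", n=n_bootstrap, seed=int(s_max)),
        ci95_min=bootstrap_ci(series, "negative_cog", n=n_bootstrap,
                              seed=int(s_min)),
        n_bootstrap=n_bootstrap,
    )
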