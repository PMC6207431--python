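"""Monthly death rates: population interpolation and month-length correction.

Yearly population counts are anchored to July and linearly interpolated to
months; monthly death counts are rescaled to a standard 31-day month before
rates (per 100,000) are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .dataio import StratumKey
from .errors import SchemaError

RATE_SCALE = 100_000.0
STANDARD_MONTH_DAYS = 31.0


@dataclass
class MonthlySeries:
    """A monthly series (rate per 100,000 per 31-day month, or raw counts).

    ``values`` carries a contiguous monthly :class:`pandas.PeriodIndex`.
    """

    values: pd.Series
    stratum: StratumKey | None = None
    corrected: bool = False
    is_rate: bool = True

    def __post_init__(self):
        idx = self.values.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise SchemaError("MonthlySeries requires a monthly PeriodIndex")
        if len(idx):
            full = pd.period_range(idx[0], idx[-1], freq="M")
            if len(idx) != len(full) or not (idx == full).all():
                raise SchemaError(
                    "MonthlySeries index must be contiguous and sorted")
        if (self.values < 0).any():
            raise SchemaError("negative values in MonthlySeries")


def as_series(series) -> pd.Series:
    """Accept a MonthlySeries or a bare pandas Series."""
    return series.values if isinstance(series, MonthlySeries) else series


def _month_number(index: pd.PeriodIndex) -> np.ndarray:
    # months since year 0, so July of year y is 12*y + 6
    return index.year.to_numpy() * 12 + (index.month.to_numpy() - 1)


def interpolate_population_monthly(yearly: pd.Series,
                                   index: pd.PeriodIndex | None = None) -> pd.Series:
    """Linearly interpolate yearly populations to months, anchoring at July.

    ``yearly`` is indexed by calendar year; July of each year takes the yearly
    value exactly, months between Julys are linear, and months outside the
    anchored range are extrapolated from the two nearest anchors.  By default
    the output spans January of the first anchor year through December of the
    last.
    """
    yearly = yearly.sort_index()
    if len(yearly) < 2:
        raise SchemaError("need at least 2 yearly population anchors")
    years = yearly.index.to_numpy(dtype=int)
    if index is None:
        index = pd.period_range(f"{years[0]}-01", f"{years[-1]}-12", freq="M")
    anchors_x = years * 12 + 6  # July
    f = interp1d(anchors_x, yearly.to_numpy(dtype=float),
                 kind="linear", fill_value="extrapolate", assume_sorted=True)
    values = f(_month_number(index))
    if (values <= 0).any():
        raise SchemaError("interpolated/extrapolated population is non-positive")
    return pd.Series(values, index=index, name="population")


def month_length_correct(counts) -> pd.Series:
    """Rescale monthly counts to a standard 31-day month (leap-year aware)."""
    s = as_series(counts)
    if (s < 0).any():
        raise SchemaError("negative counts")
    days = s.index.days_in_month.to_numpy(dtype=float)
    return s * (STANDARD_MONTH_DAYS / days)


def compute_death_rates(corrected_counts, population: pd.Series,
                        stratum: StratumKey | None = None) -> MonthlySeries:
    """Death rate per 100,000 from month-length-corrected counts."""
    counts = as_series(corrected_counts)
    if not counts.index.equals(population.index):
        raise SchemaError("count and population indices do not align")
    rate = counts / population * RATE_SCALE
    return MonthlySeries(values=rate.rename("rate"), stratum=stratum,
                         corrected=True, is_rate=True)
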