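"""Population-weighted regional aggregation of gridded temperature fields."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)


def population_weighted_monthly_temperature(
    grid: pd.DataFrame,
    weights: dict[str, float],
    cell_regions: dict[str, str],
) -> pd.DataFrame:
    """Monthly regional means of a sub-daily gridded field.

    ``grid`` is long format (cell, timestamp, temp_c) with equally weighted
    sub-daily samples.  Cell-month means are combined into regional means
    using population weights normalised within each region.  Returns a
    DataFrame (region, year, month, temp_c).
    """
    for col in ("cell", "timestamp", "temp_c"):
        if col not in grid.columns:
            raise SchemaError(f"grid missing column {col!r}")
    df = grid.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["year"] = ts.dt.year
    df["month"] = ts.dt.month
    cell_means = (
        df.groupby(["cell", "year", "month"], observed=True)["temp_c"]
        .mean().reset_index()
    )
    cell_means["region"] = cell_means["cell"].map(cell_regions)
    if cell_means["region"].isna().any():
        missing = cell_means.loc[cell_means["region"].isna(), "cell"].unique()
        raise SchemaError(f"cells without a region: {sorted(missing)}")
    cell_means["weight"] = cell_means["cell"].map(weights).fillna(0.0)

    def _weighted(g: pd.DataFrame) -> float:
        total = g["weight"].sum()
        if total <= 0:
            raise SchemaError(
                f"region {g.name[0]!r} has zero total population weight"
            )
        return float(np.average(g["temp_c"], weights=g["weight"]))

    out = (
        cell_means.groupby(["region", "year", "month"], observed=True)
        .apply(_weighted, include_groups=False)
        .rename("temp_c").reset_index()
    )
    return out


@dataclass
class Climatology:
    """Long-run summaries of regional monthly temperatures."""

    monthly: pd.DataFrame      # index region, columns month 1..12
    annual_mean: pd.Series     # per region
    annual_range: pd.Series    # max - min of the monthly climatology
    peak_month: pd.Series      # warmest month of the climatology

    def region_months(self, region: str) -> dict[int, float]:
        if region not in self.monthly.index:
            raise SchemaError(f"no climatology for region {region!r}")
        return self.monthly.loc[region].to_dict()


def regional_climatology(temps: pd.DataFrame) -> Climatology:
    """Per-region annual mean, per-month long-run mean and annual range.

    Incomplete years (fewer than 12 months for a region) are excluded with a
    warning.
    """
    for col in ("region", "year", "month", "temp_c"):
        if col not in temps.columns:
            raise SchemaError(f"temperature table missing column {col!r}")
    counts = temps.groupby(["region", "year"], observed=True)["month"].nunique()
    incomplete = counts[counts < 12]
    if len(incomplete):
        logger.warning("excluding incomplete region-years: %s",
                       list(incomplete.index))
        keep = temps.set_index(["region", "year"]).index.isin(
            counts[counts == 12].index
        )
        temps = temps.loc[keep]
    if temps.empty:
        raise SchemaError("no complete years of regional temperatures")
    monthly = (
        temps.groupby(["region", "month"], observed=True)["temp_c"]
        .mean().unstack("month")
    )
    return Climatology(
        monthly=monthly,
        annual_mean=monthly.mean(axis=1),
        annual_range=monthly.max(axis=1) - monthly.min(axis=1),
        peak_month=monthly.idxmax(axis=1),
    )
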