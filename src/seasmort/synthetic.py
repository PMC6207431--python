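"""Synthetic death, population and temperature data with known structure.

The generator emulates the statistical structure of national vital-statistics
inputs: monthly death counts are Poisson with a multiplicative mean model

    mu(y, m) = pop(y, m) * baseline_rate * exp(trend * (y - y0))
               * (1 + sum_k A_k(y) * cos(2*pi*(m - phase_k) / period_k))
               * days_in_month / 31        (if month_length_effect)

where ``pop(y, m)`` is the July-anchored monthly interpolation of a
deterministic exponentially growing yearly population, and each seasonal
component's amplitude ``A_k(y)`` optionally halves every
``amplitude_halflife`` years (emulating seasonality that fades over the
study period).  Everything is reproducible from ``rng_seed``.

A companion generator produces a gridded four-times-daily temperature field
with a sinusoidal annual cycle per region plus Gaussian noise, in the shape
consumed by :mod:`seasmort.temperature`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DEATH_COLUMNS, LEAF_CATEGORIES, POPULATION_COLUMNS, StratumKey
from .errors import ConfigError
from .rates import interpolate_population_monthly


@dataclass(frozen=True)
class SeasonalComponent:
    """One sinusoidal seasonal component of the death-rate model.

    amplitude : relative amplitude (0.2 means +/-20% around baseline)
    phase     : peak month in [1, 12] (may be fractional)
    period    : period in months, 12 (annual) or 6 (semi-annual)
    amplitude_halflife : years for the amplitude to halve; None = constant
    """

    amplitude: float
    phase: float
    period: int = 12
    amplitude_halflife: float | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError("seasonal amplitude must be >= 0")
        if not 1 <= self.phase <= 12:
            raise ConfigError("seasonal phase (peak month) must lie in [1, 12]")
        if self.period not in (12, 6):
            raise ConfigError("seasonal period must be 12 or 6 months")
        if self.amplitude_halflife is not None and self.amplitude_halflife <= 0:
            raise ConfigError("amplitude_halflife must be positive")

    def amplitude_at(self, years_elapsed: float) -> float:
        if self.amplitude_halflife is None:
            return self.amplitude
        return self.amplitude * 2.0 ** (-years_elapsed / self.amplitude_halflife)


@dataclass
class StratumSpec:
    """Mean-model parameters for one simulated stratum.

    ``baseline_rate`` is in deaths per person-month; ``trend`` is the
    log-linear slope of the rate per year.  The stratum's cause must be a
    leaf category so the output table satisfies the cause-partition property.
    """

    stratum: StratumKey
    baseline_rate: float
    trend: float = 0.0
    components: list[SeasonalComponent] = field(default_factory=list)
    population_start: float = 100_000.0
    population_growth: float = 0.0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be positive")
        if self.population_start <= 0:
            raise ConfigError("population_start must be positive")
        if self.stratum.cause not in LEAF_CATEGORIES:
            raise ConfigError(
                "simulated strata must use a leaf cause category, got "
                f"{self.stratum.cause!r}"
            )

    def seasonal_factor(self, years_elapsed: float, month: np.ndarray) -> np.ndarray:
        factor = np.ones_like(np.asarray(month, dtype=float))
        for comp in self.components:
            a = comp.amplitude_at(years_elapsed)
            factor = factor + a * np.cos(
                2 * np.pi * (month - comp.phase) / comp.period
            )
        return factor


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic death/population generator."""

    strata: list[StratumSpec]
    years: tuple[int, int] = (1980, 2016)
    month_length_effect: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigError("years range is empty")
        if not self.strata:
            raise ConfigError("no strata to simulate")
        months = np.arange(1, 13)
        for spec in self.strata:
            # amplitudes are largest in the first year; a negative seasonal
            # factor there means a negative Poisson mean somewhere
            if spec.seasonal_factor(0.0, months).min() < 0:
                raise ConfigError(
                    f"seasonal components of {spec.stratum} drive the mean "
                    "negative in some month"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        strata = []
        for s in d["strata"]:
            comps = [SeasonalComponent(**c) for c in s.get("components", [])]
            strata.append(StratumSpec(
                stratum=StratumKey(**s["stratum"]),
                baseline_rate=s["baseline_rate"],
                trend=s.get("trend", 0.0),
                components=comps,
                population_start=s.get("population_start", 100_000.0),
                population_growth=s.get("population_growth", 0.0),
            ))
        return cls(
            strata=strata,
            years=tuple(d.get("years", (1980, 2016))),
            month_length_effect=d.get("month_length_effect", True),
            rng_seed=d.get("rng_seed", 0),
        )


def _population_key(spec: StratumSpec):
    s = spec.stratum
    return (s.region, s.age_group, s.sex)


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic yearly populations: pop(y) = start * (1+growth)^(y-y0).

    One row per (year, region, age group, sex); cause-specific strata sharing
    a demographic cell must agree on the population parameters.
    """
    y0, y1 = config.years
    seen: dict[tuple, tuple[float, float]] = {}
    for spec in config.strata:
        key = _population_key(spec)
        params = (spec.population_start, spec.population_growth)
        if seen.setdefault(key, params) != params:
            raise ConfigError(
                f"inconsistent population parameters for demographic cell {key}"
            )
    rows = []
    years = np.arange(y0, y1 + 1)
    for (region, age_group, sex), (start, growth) in seen.items():
        pop = start * (1.0 + growth) ** (years - y0)
        for y, p in zip(years, pop):
            rows.append((int(y), region, age_group, sex, float(p)))
    return pd.DataFrame(rows, columns=list(POPULATION_COLUMNS))


def _monthly_population(population: pd.DataFrame, spec: StratumSpec,
                        years: tuple[int, int]) -> pd.Series:
    s = spec.stratum
    sub = population[
        (population["region"] == s.region)
        & (population["age_group"] == s.age_group)
        & (population["sex"] == s.sex)
    ]
    yearly = sub.set_index("year")["population"].sort_index()
    y0, y1 = years
    if yearly.empty or yearly.index.min() > y0 or yearly.index.max() < y1:
        raise ConfigError(f"population does not cover {y0}-{y1} for {s}")
    index = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    return interpolate_population_monthly(yearly, index=index)


def expected_deaths(config: SimulationConfig, spec: StratumSpec,
                    population: pd.DataFrame) -> pd.Series:
    """The exact Poisson mean mu(y, m) for one stratum (no noise)."""
    y0, _ = config.years
    pop = _monthly_population(population, spec, config.years)
    idx = pop.index
    month = idx.month.to_numpy(dtype=float)
    # fractional years elapsed at mid-month, so decay is smooth within years
    elapsed = (idx.year.to_numpy() - y0) + (month - 0.5) / 12.0
    seasonal = np.array([
        spec.seasonal_factor(e, m) for e, m in zip(elapsed, month)
    ])
    mu = pop.to_numpy() * spec.baseline_rate \
        * np.exp(spec.trend * (idx.year.to_numpy() - y0)) * seasonal
    if config.month_length_effect:
        mu = mu * idx.days_in_month.to_numpy() / 31.0
    return pd.Series(mu, index=idx, name="mu")


def simulate_deaths(config: SimulationConfig,
                    population: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw monthly Poisson death counts for every configured stratum."""
    if population is None:
        population = simulate_population(config)
    rng = np.random.default_rng(config.rng_seed)
    frames = []
    for spec in config.strata:
        mu = expected_deaths(config, spec, population)
        counts = rng.poisson(mu.to_numpy())
        s = spec.stratum
        frames.append(pd.DataFrame({
            "year": mu.index.year,
            "month": mu.index.month,
            "region": s.region,
            "age_group": s.age_group,
            "sex": s.sex,
            "cause": s.cause,
            "count": counts,
        }))
    return pd.concat(frames, ignore_index=True)[list(DEATH_COLUMNS)]


# ---------------------------------------------------------------------------
# gridded temperature field


@dataclass(frozen=True)
class TempCell:
    cell_id: str
    region: str
    weight: float

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigError("cell population weight must be >= 0")


@dataclass(frozen=True)
class RegionClimate:
    """Annual temperature cycle of one region: mean, range, peak month, noise."""

    mean_c: float
    range_c: float
    peak_month: float = 7.0
    noise_sd: float = 0.0


@dataclass
class TempFieldConfig:
    cells: list[TempCell]
    climate: dict[str, RegionClimate]
    samples_per_day: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        for region in self.climate:
            if not any(c.region == region and c.weight > 0 for c in self.cells):
                raise ConfigError(
                    f"region {region!r} has no cell with positive weight"
                )


def simulate_temperature(config: TempFieldConfig,
                         years: tuple[int, int]) -> pd.DataFrame:
    """Four-times-daily cell temperatures with a sinusoidal annual cycle.

    Each sample is ``mean + (range/2) * cos(2*pi*(month - peak)/12)`` plus
    independent Gaussian noise.  Output is long format (cell, timestamp,
    temp_c), deterministic under ``rng_seed``.
    """
    y0, y1 = years
    step = 24 // config.samples_per_day
    stamps = pd.date_range(f"{y0}-01-01", f"{y1}-12-31 23:00", freq=f"{step}h")
    month = stamps.month.to_numpy(dtype=float)
    rng = np.random.default_rng(config.rng_seed)
    frames = []
    for cell in config.cells:
        clim = config.climate[cell.region]
        base = clim.mean_c + (clim.range_c / 2.0) * np.cos(
            2 * np.pi * (month - clim.peak_month) / 12.0
        )
        if clim.noise_sd > 0:
            base = base + rng.normal(0.0, clim.noise_sd, size=base.shape)
        frames.append(pd.DataFrame({
            "cell": cell.cell_id, "timestamp": stamps, "temp_c": base,
        }))
    return pd.concat(frames, ignore_index=True)
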