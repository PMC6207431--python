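"""End-to-end orchestration: simulate or load data, then run every stage.

A run is described by a plain-text (YAML) config naming either input tables
or a simulation, the analysis window, the strata to analyse, and options for
the wavelet test and the bootstrap.  All randomness flows through two named
seeds (``simulation`` and ``inference``) that are recorded, together with a
hash of the config, in the run metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circular, dataio, rates, synthetic, temperature, trend, wavelet
from .errors import ConfigError, SeasmortError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    window: tuple[int, int]
    analysis_strata: list[dataio.StratumKey]
    simulation: synthetic.SimulationConfig | None = None
    deaths_path: str | None = None
    population_path: str | None = None
    cause_map_path: str | None = None
    temperature_field: synthetic.TempFieldConfig | None = None
    wavelet_degree: int = 4
    wavelet_n_sims: int = 100
    bootstrap_n: int = 1000
    simulation_seed: int = 0
    inference_seed: int = 0
    output_dir: str | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        has_sim = "simulation" in d
        has_real = "inputs" in d
        if has_sim == has_real:
            raise ConfigError(
                "config must specify exactly one of 'simulation' or 'inputs'"
            )
        seeds = d.get("seeds", {})
        sim_seed = int(seeds.get("simulation", 0))
        inf_seed = int(seeds.get("inference", 0))
        sim = None
        deaths_path = population_path = cause_map_path = None
        if has_sim:
            sim_dict = dict(d["simulation"])
            sim_dict.setdefault("rng_seed", sim_seed)
            sim_dict.setdefault("years", d.get("window", (1980, 2016)))
            sim = synthetic.SimulationConfig.from_dict(sim_dict)
        else:
            inputs = d["inputs"]
            deaths_path = inputs["deaths"]
            population_path = inputs["population"]
            cause_map_path = inputs.get("cause_map")
        strata = [dataio.StratumKey(**s) for s in d["strata"]]
        temp_cfg = None
        if "temperature_field" in d:
            t = d["temperature_field"]
            temp_cfg = synthetic.TempFieldConfig(
                cells=[synthetic.TempCell(**c) for c in t["cells"]],
                climate={k: synthetic.RegionClimate(**v)
                         for k, v in t["climate"].items()},
                samples_per_day=t.get("samples_per_day", 4),
                rng_seed=t.get("rng_seed", sim_seed),
            )
        wav = d.get("wavelet", {})
        boot = d.get("bootstrap", {})
        return cls(
            window=tuple(d.get("window", (1980, 2016))),
            analysis_strata=strata,
            simulation=sim,
            deaths_path=deaths_path,
            population_path=population_path,
            cause_map_path=cause_map_path,
            temperature_field=temp_cfg,
            wavelet_degree=int(wav.get("degree", 4)),
            wavelet_n_sims=int(wav.get("n_sims", 100)),
            bootstrap_n=int(boot.get("n", 1000)),
            simulation_seed=sim_seed,
            inference_seed=inf_seed,
            output_dir=d.get("output_dir"),
            raw=d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stratum_population(population: pd.DataFrame,
                       stratum: dataio.StratumKey) -> pd.Series:
    """Yearly population for a stratum's demographic cell (regions summed
    when the stratum is national)."""
    sel = (
        (population["age_group"] == stratum.age_group)
        & (population["sex"] == stratum.sex)
    )
    if stratum.region != "national":
        sel &= population["region"] == stratum.region
    sub = population.loc[sel]
    if sub.empty:
        raise SeasmortError(f"no population rows for {stratum}")
    return sub.groupby("year")["population"].sum().sort_index()


def analyse_stratum(deaths: pd.DataFrame, population: pd.DataFrame,
                    stratum: dataio.StratumKey, window: tuple[int, int],
                    *, wavelet_degree: int = 4, wavelet_n_sims: int = 100,
                    bootstrap_n: int = 1000, seed=None) -> dict:
    """Rates, wavelet test, timing and trend for one stratum."""
    counts = dataio.aggregate_series(deaths, stratum, window)
    if counts.sum() == 0:
        raise SeasmortError(f"stratum {stratum} has no deaths in the window")
    corrected = rates.month_length_correct(counts)
    yearly_pop = stratum_population(population, stratum)
    monthly_pop = rates.interpolate_population_monthly(yearly_pop,
                                                       index=counts.index)
    series = rates.compute_death_rates(corrected, monthly_pop, stratum=stratum)

    ss = np.random.SeedSequence(seed)
    wav_seed, cog_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))
    wres = wavelet.seasonality_test(series, degree=wavelet_degree,
                                    n_sims=wavelet_n_sims, seed=wav_seed)
    cog = circular.cog_analysis(series, stratum=stratum,
                                n_bootstrap=bootstrap_n, seed=cog_seed)
    diffs = trend.yearly_percent_difference(series, counts)
    tfit = trend.fit_weighted_trend(diffs)
    return {
        "stratum": stratum, "series": series, "wavelet": wres,
        "cog": cog, "diffs": diffs, "trend": tfit,
    }


def _stratum_cols(stratum: dataio.StratumKey) -> dict:
    return {"age_group": stratum.age_group, "sex": stratum.sex,
            "cause": stratum.cause, "region": stratum.region}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every requested stratum.

    Strata that fail are logged and skipped; the bundle contains the summary
    tables (wavelet p-values, timing, trends, regional temperatures) plus run
    metadata.  Deterministic given the two seeds.
    """
    if config.simulation is not None:
        population = synthetic.simulate_population(config.simulation)
        deaths = synthetic.simulate_deaths(config.simulation, population)
    else:
        cause_map = (dataio.CauseMap.from_csv(config.cause_map_path)
                     if config.cause_map_path else None)
        deaths = dataio.load_deaths(config.deaths_path, cause_map=cause_map)
        population = dataio.load_population(config.population_path)

    ss = np.random.SeedSequence(config.inference_seed)
    stratum_seeds = ss.generate_state(len(config.analysis_strata)) % (2 ** 31)

    wavelet_rows, cog_rows, trend_rows, yearly_frames = [], [], [], []
    skipped = []
    for stratum, seed in zip(config.analysis_strata, stratum_seeds):
        try:
            res = analyse_stratum(
                deaths, population, stratum, config.window,
                wavelet_degree=config.wavelet_degree,
                wavelet_n_sims=config.wavelet_n_sims,
                bootstrap_n=config.bootstrap_n, seed=int(seed),
            )
        except SeasmortError as exc:
            logger.warning("skipping stratum %s: %s", stratum, exc)
            skipped.append({"stratum": str(stratum), "reason": str(exc)})
            continue
        cols = _stratum_cols(stratum)
        wres, cog, tfit = res["wavelet"], res["cog"], res["trend"]
        wavelet_rows.append({
            **cols, "p12": wres.p12, "n_sims": wres.n_sims,
            "band_power_12m": wres.band_power(12.0),
        })
        cog_rows.append({
            **cols,
            "max_month": cog.max_timing.month,
            "max_month_nearest": cog.max_timing.nearest_month,
            "max_ci_lo": cog.ci95_max.lo, "max_ci_hi": cog.ci95_max.hi,
            "max_circ_variance": cog.max_timing.circular_variance,
            "min_month": cog.min_timing.month,
            "min_month_nearest": cog.min_timing.nearest_month,
            "min_ci_lo": cog.ci95_min.lo, "min_ci_hi": cog.ci95_min.hi,
            "min_circ_variance": cog.min_timing.circular_variance,
            "n_bootstrap": cog.n_bootstrap,
        })
        trend_rows.append({
            **cols, "slope": tfit.slope, "slope_se": tfit.slope_se,
            "p_value": tfit.p_value, "fitted_start": tfit.fitted_start,
            "fitted_end": tfit.fitted_end, "change": tfit.change,
        })
        ytab = trend.trend_table(res["diffs"])
        for k, v in cols.items():
            ytab[k] = v
        yearly_frames.append(ytab)

    bundle = {
        "wavelet": pd.DataFrame(wavelet_rows),
        "cog": pd.DataFrame(cog_rows),
        "trend": pd.DataFrame(trend_rows),
        "yearly": (pd.concat(yearly_frames, ignore_index=True)
                   if yearly_frames else pd.DataFrame()),
        "skipped": skipped,
        "metadata": {
            "config_hash": config.config_hash(),
            "seeds": {"simulation": config.simulation_seed,
                      "inference": config.inference_seed},
            "window": list(config.window),
            "n_strata": len(config.analysis_strata),
            "n_skipped": len(skipped),
        },
    }

    if config.temperature_field is not None:
        grid = synthetic.simulate_temperature(config.temperature_field,
                                              config.window)
        weights = {c.cell_id: c.weight for c in config.temperature_field.cells}
        cell_regions = {c.cell_id: c.region
                        for c in config.temperature_field.cells}
        bundle["temperature"] = temperature.population_weighted_monthly_temperature(
            grid, weights, cell_regions
        )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("wavelet", "cog", "trend", "yearly"):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
        if "temperature" in bundle:
            bundle["temperature"].to_csv(out / "temperature.csv", index=False)
        with open(out / "run_metadata.json", "w") as fh:
            json.dump({**bundle["metadata"], "skipped": skipped}, fh, indent=2)
    return bundle
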