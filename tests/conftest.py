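import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from seasmort import dataio, rates, synthetic

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


DEFAULT_KEY = dataio.StratumKey("65-74", "male", "cardiovascular", "national")


def make_config(*, baseline=500.0, amplitude=0.2, phase=1.0, halflife=None,
                period=12, trend=0.0, years=(1980, 2016), pop=1e7,
                growth=0.0, seed=0, key=DEFAULT_KEY, month_length_effect=True):
    """One-stratum simulation config with a planted seasonal signal.

    ``baseline`` is in expected deaths per month (converted to a per-person
    rate against ``pop``).
    """
    comps = []
    if amplitude > 0:
        comps = [synthetic.SeasonalComponent(
            amplitude=amplitude, phase=phase, period=period,
            amplitude_halflife=halflife,
        )]
    spec = synthetic.StratumSpec(
        stratum=key, baseline_rate=baseline / pop, trend=trend,
        components=comps, population_start=pop, population_growth=growth,
    )
    return synthetic.SimulationConfig(
        strata=[spec], years=years, rng_seed=seed,
        month_length_effect=month_length_effect,
    )


def planted_series(**kwargs):
    """Simulate one stratum end to end; return (rate series, raw counts,
    corrected counts) through the full dataio/rates path."""
    cfg = make_config(**kwargs)
    key = kwargs.get("key", DEFAULT_KEY)
    years = kwargs.get("years", (1980, 2016))
    pop_df = synthetic.simulate_population(cfg)
    deaths = synthetic.simulate_deaths(cfg, pop_df)
    counts = dataio.aggregate_series(deaths, key, years)
    corrected = rates.month_length_correct(counts)
    yearly = pop_df.groupby("year")["population"].sum().sort_index()
    monthly_pop = rates.interpolate_population_monthly(yearly,
                                                       index=counts.index)
    series = rates.compute_death_rates(corrected, monthly_pop, stratum=key)
    return series, counts, corrected


@pytest.fixture
def stratum_key():
    return DEFAULT_KEY


@pytest.fixture
def monthly_index():
    def _make(y0=1980, y1=2016):
        return pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    return _make


@pytest.fixture
def cosine_rate_series(monthly_index):
    """Noise-free cosine-seasonal rate series with a January peak."""
    def _make(amplitude=0.3, phase=1.0, y0=1980, y1=2016, level=100.0):
        idx = monthly_index(y0, y1)
        m = idx.month.to_numpy(dtype=float)
        values = level * (1 + amplitude * np.cos(2 * np.pi * (m - phase) / 12))
        return pd.Series(values, index=idx)
    return _make
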