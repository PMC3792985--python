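import numpy as np
import pandas as pd
import pytest

from frostbloom import ScenarioConfig, gen_climate_ensemble
from frostbloom.climate_prep import TemperatureSeries


@pytest.fixture(scope="session")
def baseline_series():
    """One 33-year no-trend realization at a single grid point."""
    cfg = ScenarioConfig(n_runs=1, n_grid=1, years=(1969, 2001), seed=5,
                         warming_per_century=0.0, warming_spread=0.0,
                         run_bias=0.0)
    return gen_climate_ensemble(cfg)[0]


@pytest.fixture(scope="session")
def warming_series():
    """One 150-year +3 K/century realization at a single grid point."""
    cfg = ScenarioConfig(n_runs=1, n_grid=1, years=(1951, 2100), seed=7,
                         warming_per_century=3.0, warming_spread=0.0,
                         run_bias=0.0)
    return gen_climate_ensemble(cfg)[0]


@pytest.fixture(scope="session")
def small_ensemble():
    """5 runs x 2 grid points, 1951-2100, A1B-like warming."""
    cfg = ScenarioConfig(n_runs=5, n_grid=2, seed=2)
    return gen_climate_ensemble(cfg)


def constant_season(temp: float, year: int = 2000):
    """A phenological year of constant daily temperature."""
    time = pd.date_range(f"{year - 1}-08-01", f"{year}-07-31", freq="D")
    doy = time.dayofyear.values
    tmean = np.full(time.size, float(temp))
    return tmean, doy
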