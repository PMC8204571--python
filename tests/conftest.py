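import numpy as np
import pandas as pd
import pytest

from heatmort.series import DailyCitySeries, summer_dates
from heatmort.simulate import SimulationConfig, generate_present_series


def single_city_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Seoul-only configuration under the reference study conditions."""
    cfg = SimulationConfig.reference_six_cities(seed=seed, **overrides)
    return SimulationConfig(cities=cfg.cities[:1], years=cfg.years, seed=seed)


@pytest.fixture(scope="session")
def seoul_sim():
    """One Seoul-like simulated present-day dataset (8 summers, seed 42)."""
    return generate_present_series(single_city_config(seed=42))


@pytest.fixture(scope="session")
def seoul_series(seoul_sim):
    return seoul_sim.series[0]


def series_from_temps(temps, city="testville", year=2001, **extra_cols):
    """Wrap a <=122-long temperature array into a one-summer DailyCitySeries."""
    temps = np.asarray(temps, dtype=float)
    n = len(temps)
    dates = summer_dates(year)[:n]
    df = pd.DataFrame({"date": dates, "tmean_c": temps, **extra_cols})
    return DailyCitySeries(city=city, data=df)
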