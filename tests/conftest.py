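import numpy as np
import pandas as pd
import pytest

from aqcausal.synthetic import SimConfig, generate_weather, generate_site_series


@pytest.fixture(scope="session")
def small_config():
    """Short, quiet world for unit tests (not the acceptance world)."""
    return SimConfig(
        n_sites=2,
        start="2019-06-01",
        end="2020-09-30",
        t0="2020-03-23",
        true_tau=-0.15,
        noise_sd=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    weather = generate_weather(small_config)
    conc, truth = generate_site_series(small_config, weather)
    return {"config": small_config, "weather": weather, "conc": conc, "truth": truth}


@pytest.fixture
def daily_index():
    def make(n, start="2019-06-01"):
        return pd.date_range(start, periods=n, freq="D")

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
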