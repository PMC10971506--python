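import numpy as np
import pandas as pd
import pytest

from ebullition import SyntheticConfig, gen_drivers, gen_ebullition


@pytest.fixture(scope="session")
def small_config():
    """Three warm-season months at hourly resolution — fast but long enough
    for daily aggregation, synchrony and driver statistics."""
    return SyntheticConfig(seed=7, start="2018-12-01", end="2019-03-01",
                           base_interval="1h")


@pytest.fixture(scope="session")
def small_drivers(small_config):
    return gen_drivers(small_config)


@pytest.fixture(scope="session")
def small_fluxes(small_config, small_drivers):
    return gen_ebullition(small_drivers, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_series(values, start="2019-01-01 01:00", interval="1h", **kw):
    from ebullition import RegularSeries

    return RegularSeries(start=pd.Timestamp(start), interval=interval,
                         values=np.asarray(values, dtype=float), **kw)
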