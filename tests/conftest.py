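import numpy as np
import pytest

from vespasam import pipeline as pl
from vespasam import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """A light 12x12 km landscape used by most unit tests."""
    return sim.LandscapeConfig(
        extent=(12.0, 12.0),
        coarse_cell=1.0,
        fine_cell=0.05,
        landcover_block_km=0.2,
        climate_corr_km=3.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated study on the small landscape (120 sites, 10 units)."""
    return pl.simulate_dataset(0, config=small_config, n_sites=120, n_units=10)


@pytest.fixture(scope="session")
def site_table(small_dataset):
    return small_dataset["table"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
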