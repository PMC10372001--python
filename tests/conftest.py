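import numpy as np
import pytest

from cropdep import GridSpec, WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact noise-free synthetic world shared across read-only tests."""
    return generate_world(WorldConfig(nlat=6, nlon=8, refine=2, n_countries=3, seed=11))


@pytest.fixture
def global_1deg():
    return GridSpec(np.arange(-89.5, 90, 1.0), np.arange(-179.5, 180, 1.0))


def random_grid(rng, max_n=8, lat_span=(-60.0, 60.0), lon_span=(-120.0, 120.0)):
    """Small random regular grid for property tests."""
    nlat = int(rng.integers(2, max_n))
    nlon = int(rng.integers(2, max_n))
    dlat = (lat_span[1] - lat_span[0]) / nlat
    dlon = (lon_span[1] - lon_span[0]) / nlon
    return GridSpec(lat_span[0] + dlat * (np.arange(nlat) + 0.5),
                    lon_span[0] + dlon * (np.arange(nlon) + 0.5))
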