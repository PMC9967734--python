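import numpy as np
import pytest

from greenrisk import SyntheticConfig
from greenrisk.raster import Raster
from greenrisk.synthetic import (evolve_landscape, generate_base_landscape,
                                 generate_drivers)


def make_raster(values, cell_size_m=1000.0, nodata=0):
    values = np.asarray(values)
    return Raster(values, cell_size_m=cell_size_m,
                  y0=values.shape[0] * cell_size_m, nodata=nodata)


@pytest.fixture(scope="session")
def desk_config():
    """Desk-scale synthetic configuration used by the recovery tests."""
    return SyntheticConfig(n_rows=300, n_cols=300, seed=42)


@pytest.fixture(scope="session")
def desk_landscape(desk_config):
    base = generate_base_landscape(desk_config)
    epoch2 = evolve_landscape(base, desk_config)
    return base, epoch2


@pytest.fixture(scope="session")
def desk_drivers(desk_config, desk_landscape):
    return generate_drivers(desk_config, desk_landscape[0])


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_rows=80, n_cols=80, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    base = generate_base_landscape(small_config)
    return base, evolve_landscape(base, small_config)
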