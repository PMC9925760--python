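import numpy as np
import pytest

from bloomweb import GridSpec, gen_foodweb
from bloomweb.synthetic import DRIVER_VARS, DriverStack

UNIFORM_VALUES = dict(
    depth=20.0, rugosity=0.5, sst=25.0, sbt=23.0, sss=35.0, chlorophyll=1.0
)


def make_uniform_drivers(grid: GridSpec, n_months: int) -> DriverStack:
    """Constant-in-time, spatially uniform drivers: the baseline forcing."""
    data = {}
    for v in DRIVER_VARS:
        a = np.full((n_months, grid.n_rows, grid.n_cols), UNIFORM_VALUES[v])
        a[:, grid.land_mask] = np.nan
        data[v] = a
    return DriverStack(grid=grid, data=data, n_months=n_months)


@pytest.fixture(scope="session")
def model10():
    return gen_foodweb(10, 2, seed=42)


@pytest.fixture(scope="session")
def model8():
    return gen_foodweb(8, 1, seed=2)


@pytest.fixture()
def grid6():
    return GridSpec.regular(6, 6)


@pytest.fixture()
def one_cell_grid():
    """A grid with exactly one water cell."""
    mask = np.ones((2, 2), dtype=bool)
    mask[0, 1] = False
    return GridSpec(2, 2, 5.0, mask)


@pytest.fixture()
def uniform_drivers():
    return make_uniform_drivers
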