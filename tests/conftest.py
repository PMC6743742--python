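import numpy as np
import pytest

from popgrid import WorldConfig, simulate_world
from popgrid.covariates_static import pixel_area_grid
from popgrid.dasymetric import CovariateStack
from popgrid.grid import GridRaster, Mastergrid, define_mastergrid


@pytest.fixture(scope="session")
def world42():
    """Default 100x100 synthetic world, seed 42 — shared, treated read-only."""
    return simulate_world(WorldConfig(seed=42))


@pytest.fixture(scope="session")
def areas42(world42):
    return pixel_area_grid(world42.grid)


@pytest.fixture(scope="session")
def counts42(world42):
    return {rec.unit_id: rec.P1 for rec in world42.census}


@pytest.fixture(scope="session")
def model_stack42(world42):
    """Covariates fed to the RF (the categorical layer is held out so the
    weighting tests exercise the continuous/binary path by default)."""
    return CovariateStack({k: v for k, v in world42.stack.layers.items()
                           if k != "landcover"})


@pytest.fixture
def grid4():
    """4x4 grid over (0,0)-(1,1) at 0.25 degrees."""
    return define_mastergrid((0.0, 0.0, 1.0, 1.0), 0.25)


def make_raster(grid: Mastergrid, values, kind="continuous", nodata=None):
    return GridRaster(grid, np.asarray(values), kind, nodata)
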