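import numpy as np
import pandas as pd
import pytest

from fragcf.landscape import LandscapeGrid, Legend
from fragcf.synth import WorldSpec, make_world


@pytest.fixture(scope="session")
def small_world():
    """One compact synthetic world shared by read-only tests."""
    return make_world(WorldSpec(seed=11, n_ecoregions=2, grid_shape=(24, 24)))


@pytest.fixture
def mini_legend():
    return Legend(pd.DataFrame([
        {"code": 0, "land_use": "natural", "intensity": "natural"},
        {"code": 1, "land_use": "cropland", "intensity": "minimal"},
        {"code": 2, "land_use": "cropland", "intensity": "intense"},
    ]))


def grid_from_array(arr, cell_size=10.0, **kw):
    return LandscapeGrid(np.asarray(arr), cell_size=cell_size, **kw)


@pytest.fixture
def make_grid():
    return grid_from_array
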