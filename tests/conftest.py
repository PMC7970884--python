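import numpy as np
import pytest

from wrastichi.config import validate_config
from wrastichi.grid import Grid
from wrastichi.scene import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def default_config():
    return validate_config(None)


@pytest.fixture(scope="session")
def quiet_scene():
    """A small noise-free three-lake scene shared across read-only tests."""
    spec = SceneSpec(shape=(72, 72), n_lakes=3, drivers=[0.1, 0.5, 0.9],
                     dem_noise=0.0, band_noise=0.0, seed=7)
    return generate_scene(spec)


def make_grid(values, cell_size=1.0, nodata=-9999.0, **kw):
    values = np.asarray(values)
    kw.setdefault("origin_y", values.shape[0] * cell_size)
    return Grid(values, cell_size=cell_size, nodata=nodata, **kw)


@pytest.fixture
def grid_factory():
    return make_grid
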