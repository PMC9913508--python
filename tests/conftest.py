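import numpy as np
import pytest

from resectmap import BinaryMask, CarveConfig, GridGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20230129)


@pytest.fixture
def unit_grid():
    """16^3 grid at 1 mm isotropic, origin at zero."""
    return GridGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(16, 16, 16))


@pytest.fixture
def fine_config():
    return CarveConfig(tool_radius_mm=1.5, grid_spacing_mm=0.5, band_mm=3.0)


def random_geometry(rng, max_shape=20, rotated=False):
    shape = tuple(int(s) for s in rng.integers(2, max_shape, size=3))
    spacing = rng.uniform(0.3, 2.5, size=3)
    origin = rng.uniform(-50, 50, size=3)
    if rotated:
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        direction = q
    else:
        direction = np.eye(3)
    return GridGeometry(origin=origin, spacing=spacing, shape=shape, direction=direction)


def random_mask(rng, geometry, p=0.3):
    return BinaryMask(geometry, rng.random(geometry.shape) < p)
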