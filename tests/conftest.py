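import numpy as np
import pytest

from trilomorph.landmarking import LandmarkConfiguration
from trilomorph.surface_io import DEM, PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def plane_cloud(rng):
    """600 scattered samples of the plane z = 2x + 3y over [0,1]^2."""
    xy = rng.uniform(0.0, 1.0, size=(600, 2))
    # pin the corners so the convex hull covers the whole unit square
    corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    xy = np.vstack([xy, corners])
    z = 2 * xy[:, 0] + 3 * xy[:, 1]
    return PointCloud(np.column_stack([xy, z]), specimen_id="plane")


@pytest.fixture
def plane_dem():
    """Exact DEM of z = 2x + 3y on a 41x41 grid over [0,1]^2."""
    n = 41
    cell = 1.0 / n
    c = (np.arange(n) + 0.5) * cell
    gx, gy = np.meshgrid(c, c)
    return DEM(2 * gx + 3 * gy, origin_x=0.0, origin_y=0.0, cell_size=cell)


def random_config(rng, k=7):
    return rng.normal(0.0, 1.0, size=(k, 2))


@pytest.fixture
def random_configs(rng):
    """20 random 7-landmark configurations as LandmarkConfiguration objects."""
    return [LandmarkConfiguration(random_config(rng), specimen_id=f"s{i}")
            for i in range(20)]
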