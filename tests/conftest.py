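import numpy as np
import pytest

from epp.density import GRID, density_grid
from epp.modal import ClusterConfig, cluster_grid, noise_floor


@pytest.fixture(scope="session")
def grid_axes():
    xs = np.arange(GRID) / (GRID - 1)
    return np.meshgrid(xs, xs, indexing="ij")


@pytest.fixture(scope="session")
def two_gauss_coords():
    """Equal-mass two-component sample separated along x."""
    rng = np.random.default_rng(99)
    a = rng.normal((0.3, 0.5), 0.02, size=(10000, 2))
    b = rng.normal((0.7, 0.5), 0.02, size=(10000, 2))
    return np.clip(np.vstack([a, b]), 0, 1)


@pytest.fixture(scope="session")
def two_gauss_partition(two_gauss_coords):
    """DensityGrid + GridLabels of the two-component fixture at W = 0.02."""
    cfg = ClusterConfig()
    grid = density_grid(two_gauss_coords, 0.02)
    thr = noise_floor(grid.density, grid.weights, grid.kernel_sd, cfg)
    labels = cluster_grid(grid.density, thr, cfg)
    return grid, labels, cfg
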