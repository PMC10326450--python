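import numpy as np
import pytest

from spatialinfo import SpatialDataset, build_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid30():
    """30x30 regular grid coordinates."""
    xx, yy = np.meshgrid(np.arange(30), np.arange(30))
    return np.c_[xx.ravel(), yy.ravel()].astype(float)


@pytest.fixture
def half_grid_dataset(grid30):
    """Binary gene: 1 on the left half of the grid, 0 on the right."""
    gene = (grid30[:, 0] < 15).astype(float)
    return SpatialDataset(counts=gene[:, None], coords=grid30, gene_ids=["half"])


@pytest.fixture
def null_dataset():
    """Spatially random NB counts: no gene has any spatial structure."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 1, (400, 2))
    counts = rng.negative_binomial(4, 4 / (4 + 5), size=(400, 5))
    return SpatialDataset(counts=counts, coords=coords)


@pytest.fixture
def square4_graph():
    """Unit-square corners with radius graph epsilon=1.1 (sides only)."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    return coords, build_graph(coords, "radius", epsilon=1.1)
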