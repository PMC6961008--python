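import numpy as np
import pytest

from crownseg.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_grid():
    """Constant 16x16 grid at 0.25 m cells."""
    return RasterGrid(np.full((16, 16), 3.0), 0.25, (0.0, 4.0))


def gaussian_cap_grid(
    n: int = 64,
    cell: float = 0.25,
    apex: float = 10.0,
    cx: float = 8.0,
    cy: float = 8.0,
    sx: float = 1.0,
    sy: float = 1.0,
    cutoff: float = 0.0,
) -> RasterGrid:
    """Analytic Gaussian crown surface on an n x n grid (origin upper-left)."""
    grid = RasterGrid(np.zeros((n, n)), cell, (0.0, n * cell))
    X, Y = grid.cell_centers()
    z = apex * np.exp(-(((X - cx) ** 2) / (2 * sx**2) + ((Y - cy) ** 2) / (2 * sy**2)))
    if cutoff > 0:
        z = np.where(z >= cutoff * apex, z, 0.0)
    return RasterGrid(z, cell, (0.0, n * cell))
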