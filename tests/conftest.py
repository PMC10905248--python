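import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nicheshift.grid import RasterGrid, RasterStack

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid30():
    """30x30 grid over a Great Plains-like window (~5.5 km cells)."""
    return RasterGrid(30, 30, 0.05, x_min=-105.0, y_max=42.0)


@pytest.fixture
def grid10():
    return RasterGrid(10, 10, 0.1, x_min=0.0, y_max=1.0)


@pytest.fixture
def gradient_stack(grid10):
    """Single-layer stack increasing west-to-east."""
    lon, _ = grid10.center_mesh()
    return RasterStack(grid10, {"x": lon})


def random_probability_pair(rng, max_side=50):
    """Two normalized surfaces on one random grid with a shared random mask."""
    nr = int(rng.integers(2, max_side + 1))
    nc = int(rng.integers(2, max_side + 1))
    grid = RasterGrid(nr, nc, 0.1)
    mask = rng.random((nr, nc)) < 0.9
    if not mask.any():
        mask[0, 0] = True
    surfaces = []
    for _ in range(2):
        v = rng.random((nr, nc)) * mask
        p = np.full((nr, nc), np.nan)
        p[mask] = v[mask] / v[mask].sum()
        surfaces.append(p)
    return grid, mask, surfaces[0], surfaces[1]
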