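import numpy as np
import pytest

from foldshape.synthetic_data import (CometMovieParams, EpitheliumParams,
                                      generate_comet_movie,
                                      generate_epithelium_stack)
from foldshape.types import CellMask2D


def random_blob_mask(rng: np.random.Generator, size: int = 40,
                     n_steps: int = 90) -> np.ndarray:
    """A random 8-connected blob inside a size×size grid (random walk dilated
    by occasional 2×2 stamps), for chord-oracle stress tests."""
    grid = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    for _ in range(n_steps):
        grid[r, c] = True
        if rng.random() < 0.3:
            grid[max(0, r - 1):r + 1, max(0, c - 1):c + 1] = True
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 0, size - 1))
        c = int(np.clip(c + dc, 0, size - 1))
    grid[r, c] = True
    return grid


@pytest.fixture
def blob_masks():
    """30 seeded random blobs as CellMask2D at unit spacing."""
    rng = np.random.default_rng(1234)
    return [CellMask2D(random_blob_mask(rng), (1.0, 1.0)) for _ in range(30)]


@pytest.fixture(scope="session")
def small_epithelium():
    """A small folded epithelium with defaults (fold 90°, ratios 0.7/0.5)."""
    params = EpitheliumParams(n_cells_per_side=2, seed=42)
    stack, labels, truth = generate_epithelium_stack(params)
    return params, stack, labels, truth


@pytest.fixture(scope="session")
def flat_epithelium():
    """A flat (fold 180°) sheet, cells aligned with y."""
    params = EpitheliumParams(n_cells_per_side=2, fold_angle=180.0, seed=42)
    stack, labels, truth = generate_epithelium_stack(params)
    return params, stack, labels, truth


@pytest.fixture(scope="session")
def comet_movie_default():
    params = CometMovieParams(seed=5)
    movie, truth = generate_comet_movie(params)
    return params, movie, truth
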