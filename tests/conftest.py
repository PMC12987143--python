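import numpy as np
import pytest

from specstack.spectra_core import (Dataset, SpectraMatrix, TraitVector,
                                    default_grid)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


def make_dataset(n, seed=0, grid=None):
    """Small random (non-leaf-like) dataset for plumbing tests."""
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    R = rng.uniform(0.05, 0.95, size=(n, len(grid)))
    y = rng.uniform(5.0, 45.0, size=n)
    ids = [f"s{i}" for i in range(n)]
    return Dataset(SpectraMatrix(ids, grid, R), TraitVector(y))


@pytest.fixture
def tiny_dataset(grid):
    return make_dataset(12, seed=42, grid=grid)
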