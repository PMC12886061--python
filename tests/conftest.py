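"""Shared fixtures: small grids, random masks, and a session-scope phantom.

Pipeline-level tests run on a coarse 32 x 32 x 24 lattice at (6, 6, 8) mm,
which covers the same 192 mm physical thorax as the default phantom at a
fraction of the cost.
"""

import numpy as np
import pytest

from reirrad import (
    CentreErrorModel,
    ImageGrid,
    PhantomParams,
    RunConfig,
    StructureMask,
    generate_case,
    simulate_centres,
)

SMALL_SIZE = (32, 32, 24)
SMALL_SPACING = (6.0, 6.0, 8.0)


@pytest.fixture
def grid20():
    return ImageGrid(origin=(0.0, 0.0, 0.0), spacing=(2.0, 2.0, 3.0), size=(20, 20, 20))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob(grid: ImageGrid, rng: np.random.Generator, n_seeds: int = 3,
                organ: str = "blob") -> StructureMask:
    """A connected-ish random mask: union of random balls, for oracle tests."""
    coords = grid.all_world_coords()
    mask = np.zeros(grid.size, dtype=bool)
    extent = np.asarray(grid.size) * np.asarray(grid.spacing)
    for _ in range(n_seeds):
        centre = rng.uniform(0.25, 0.75, size=3) * extent + np.asarray(grid.origin)
        radius = rng.uniform(0.1, 0.25) * extent.min()
        mask |= np.linalg.norm(coords - centre, axis=-1) <= radius
    if not mask.any():
        mask[tuple(np.asarray(grid.size) // 2)] = True
    return StructureMask(organ=organ, grid=grid, voxels=mask)


@pytest.fixture(scope="session")
def phantom_case():
    params = PhantomParams.for_clinical_case(0, size=SMALL_SIZE,
                                             spacing=SMALL_SPACING, seed=7)
    return generate_case(params)


@pytest.fixture(scope="session")
def submissions(phantom_case):
    return simulate_centres(phantom_case, 6, CentreErrorModel(seed=1))


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig(size=SMALL_SIZE, spacing=SMALL_SPACING, seed=0)
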