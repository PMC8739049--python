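"""Shared fixtures: small analysis grids and synthetic datasets.

Everything is generated programmatically; no data files ship with the
tests.  Grids are session-scoped because building the KD-tree and mask
index caches is the slow part.
"""

from __future__ import annotations

import numpy as np
import pytest

from alemeta.datasets import Dataset, Experiment, Focus
from alemeta.grid import VoxelGrid, make_grid, synthetic_brain_mask


@pytest.fixture(scope="session")
def brain_grid_4mm() -> VoxelGrid:
    """Brain-extent ellipsoid mask at 4 mm (fast whole-pipeline tests)."""
    return make_grid(synthetic_brain_mask(voxel_size=4.0))


@pytest.fixture(scope="session")
def box_grid_2mm() -> VoxelGrid:
    """A 20^3 all-true box at 2 mm centred on the origin (oracle tests)."""
    mask = np.ones((20, 20, 20), dtype=bool)
    affine = np.eye(4) * 2.0
    affine[3, 3] = 1.0
    affine[:3, 3] = -19.0  # centres span [-19, 19] mm
    return VoxelGrid(mask=mask, affine=affine)


def make_experiment(eid: str, n: int, foci_mm: np.ndarray) -> Experiment:
    return Experiment(id=eid, n=n,
                      foci=tuple(Focus(float(x), float(y), float(z))
                                 for x, y, z in np.atleast_2d(foci_mm)))


def random_dataset(grid: VoxelGrid, rng: np.random.Generator,
                   n_experiments: int = 14, n_foci: int = 5,
                   name: str = "random") -> Dataset:
    """Foci uniform over the in-mask voxel centres (a null dataset)."""
    exps = []
    for i in range(n_experiments):
        idx = rng.integers(0, grid.n_voxels, size=n_foci)
        exps.append(make_experiment(f"e{i:02d}", int(rng.integers(10, 60)),
                                    grid.mask_centres_mm[idx]))
    return Dataset(contrast_name=name, experiments=tuple(exps))
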