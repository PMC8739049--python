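"""Meta-analytic connectivity modelling (MACM).

Given a coordinate database of task-activation experiments and a seed
region, MACM asks which brain areas co-activate with the seed: it selects
every experiment reporting at least one focus inside the seed and runs the
corrected ALE analysis on that subset.  The seed region itself always
converges (every selected experiment has a focus there by construction);
additional clusters indicate meta-analytic co-activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset, Experiment
from .grid import VoxelGrid
from .inference import AnalysisResult, InferenceConfig, run_ale_analysis
from .kernels import KernelConfig

__all__ = ["SeedROI", "CoactivationResult", "select_by_seed", "run_macm",
           "DEFAULT_SEED_RADIUS_MM"]

DEFAULT_SEED_RADIUS_MM = 6.0


@dataclass(frozen=True)
class SeedROI:
    """A seed region: a sphere around an MNI peak, or an explicit mask volume."""

    centre: tuple[float, float, float] | None = None
    radius: float = DEFAULT_SEED_RADIUS_MM
    mask: np.ndarray | None = None  # boolean volume on the analysis grid

    def __post_init__(self) -> None:
        if self.mask is None:
            if self.centre is None:
                raise ValueError("seed needs either a sphere centre or a mask volume")
            if self.radius <= 0:
                raise ValueError("sphere radius must be positive")
        else:
            if not np.asarray(self.mask).any():
                raise ValueError("seed mask volume is empty")

    def contains(self, xyz: np.ndarray, grid: VoxelGrid) -> np.ndarray:
        """Membership test for an (n, 3) array of mm coordinates."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != grid.shape:
                raise ValueError("seed mask must live on the analysis grid")
            ijk = np.rint(grid.mm_to_vox(xyz)).astype(int)
            ok = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
            out = np.zeros(len(xyz), dtype=bool)
            out[ok] = mask[tuple(ijk[ok].T)]
            return out
        d = np.linalg.norm(xyz - np.asarray(self.centre, dtype=float), axis=1)
        return d <= self.radius

    def describe(self) -> str:
        if self.mask is not None:
            return f"mask({int(np.asarray(self.mask).sum())} voxels)"
        c = ", ".join(f"{v:g}" for v in self.centre)  # type: ignore[union-attr]
        return f"sphere(({c}) mm, r={self.radius:g} mm)"


@dataclass(frozen=True)
class CoactivationResult:
    """Selected experiment subset plus its corrected co-activation table."""

    roi: SeedROI
    selection: Dataset
    n_experiments: int
    n_subjects: int
    n_foci: int
    analysis: AnalysisResult

    def summary_frame(self) -> pd.DataFrame:
        """One-row retrieval summary (experiments / subjects / foci)."""
        return pd.DataFrame([{
            "seed": self.roi.describe(),
            "experiments": self.n_experiments,
            "subjects": self.n_subjects,
            "foci": self.n_foci,
        }])


def select_by_seed(db: Dataset, roi: SeedROI, grid: VoxelGrid) -> Dataset:
    """Experiments of *db* with at least one focus inside the seed.

    Sphere seeds use Euclidean distance <= radius; mask seeds use voxel
    membership.  Raises when nothing matches (a larger radius is the usual
    remedy).
    """
    if db.n_experiments == 0:
        raise ValueError("coordinate database is empty")
    hits: list[Experiment] = []
    for e in db.experiments:
        xyz = np.array([f.as_tuple() for f in e.foci])
        if roi.contains(xyz, grid).any():
            hits.append(e)
    if not hits:
        raise ValueError(
            f"no experiment has a focus inside the seed {roi.describe()}; "
            "consider a larger radius")
    return Dataset(contrast_name=f"macm:{roi.describe()}", experiments=tuple(hits))


def run_macm(db: Dataset, roi: SeedROI, grid: VoxelGrid,
             k: KernelConfig | None = None,
             cfg: InferenceConfig | None = None) -> CoactivationResult:
    """Corrected ALE co-activation analysis of the seed's experiment subset."""
    selection = select_by_seed(db, roi, grid)
    analysis = run_ale_analysis(selection, grid, k, cfg, warn_outside=False)
    return CoactivationResult(
        roi=roi, selection=selection,
        n_experiments=selection.n_experiments,
        n_subjects=selection.n_subjects,
        n_foci=selection.n_foci,
        analysis=analysis,
    )
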