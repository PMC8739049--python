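"""Synthetic foci datasets and coordinate databases with known ground truth.

Real coordinate-based meta-analyses draw on published peak tables and on a
licensed coordinate database, neither of which can ship with a package.
This module emulates both at the scale of a typical contrast (a handful to
~15 experiments, tens of foci, group sizes of roughly 5-100): planted
spatially convergent clusters plus uniform background foci for the
meta-analysis itself, and seed-coupled co-activation structure for MACM.
Every generator is deterministic given its seed and records the ground
truth it planted, so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, IO, Sequence

import numpy as np
import pandas as pd

from .datasets import Dataset, Experiment, Focus
from .grid import VoxelGrid

__all__ = ["SimulationSpec", "MacmSpec", "GroundTruth", "MacmGroundTruth",
           "add_planted_focus",
           "generate_dataset", "generate_macm_db", "default_sample_sizes",
           "write_ground_truth"]


def default_sample_sizes(rng: np.random.Generator, size: int) -> np.ndarray:
    """Group sizes ~ round(LogNormal(mu=3.1, sigma=0.5)) clipped to [5, 101].

    Mimics the heavy-tailed spread of group sizes seen across published
    patient-versus-control neuroimaging contrasts (roughly 5 to 100).
    """
    return np.clip(np.round(np.exp(rng.normal(3.1, 0.5, size=size))), 5, 101).astype(int)


@dataclass(frozen=True)
class SimulationSpec:
    """Generative settings for one synthetic meta-analytic contrast.

    Each experiment contributes, independently per planted centre, one
    focus at centre + isotropic Gaussian jitter with probability
    ``contribution_prob``, plus ``background_foci_per_experiment`` foci
    uniform over the in-mask voxel centres.
    """

    n_experiments: int = 14
    planted_centres: tuple[tuple[float, float, float], ...] = ()
    contribution_prob: float = 0.7
    jitter_sd_mm: float = 6.0
    background_foci_per_experiment: int | Callable[[np.random.Generator], int] = 5
    sample_size_distribution: Callable[[np.random.Generator, int], np.ndarray] = default_sample_sizes
    seed: int = 0
    contrast_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not (0.0 <= self.contribution_prob <= 1.0):
            raise ValueError("contribution_prob must lie in [0, 1]")
        if self.jitter_sd_mm < 0:
            raise ValueError("jitter_sd_mm must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: centres and, per centre, the contributing experiments."""

    planted_centres: tuple[tuple[float, float, float], ...]
    contributors: tuple[tuple[str, ...], ...]  # per centre, experiment ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (x, y, z), ids in zip(self.planted_centres, self.contributors):
            rows.append({"x": x, "y": y, "z": z,
                         "n_contributors": len(ids),
                         "contributors": ";".join(ids)})
        return pd.DataFrame(rows, columns=["x", "y", "z", "n_contributors", "contributors"])


def generate_dataset(spec: SimulationSpec, grid: VoxelGrid) -> tuple[Dataset, GroundTruth]:
    """Draw one synthetic contrast dataset and its ground-truth record.

    Planted foci falling outside the mask (jitter can push them out) are
    snapped to the nearest in-mask voxel centre, so every generated focus
    lies inside the mask.  Raises if a planted centre itself is outside.
    """
    centres = np.asarray(spec.planted_centres, dtype=float).reshape(-1, 3)
    if len(centres) and not grid.mm_in_mask(centres).all():
        bad = centres[~grid.mm_in_mask(centres)]
        raise ValueError(f"planted centres outside the mask: {bad.tolist()}")

    rng = np.random.Generator(np.random.PCG64(spec.seed))
    sample_sizes = spec.sample_size_distribution(rng, spec.n_experiments)
    experiments: list[Experiment] = []
    contributors: list[list[str]] = [[] for _ in range(len(centres))]

    for i in range(spec.n_experiments):
        eid = f"synth_{i + 1:02d}"
        foci: list[Focus] = []
        for ci, c in enumerate(centres):
            if rng.random() < spec.contribution_prob:
                p = c + rng.normal(0.0, spec.jitter_sd_mm, size=3)
                if not grid.mm_in_mask(p[None, :])[0]:
                    p = grid.nearest_mask_centre(p)[0]
                foci.append(Focus(float(p[0]), float(p[1]), float(p[2])))
                contributors[ci].append(eid)
        nb = (spec.background_foci_per_experiment(rng)
              if callable(spec.background_foci_per_experiment)
              else int(spec.background_foci_per_experiment))
        for j in rng.integers(0, grid.n_voxels, size=nb):
            x, y, z = grid.mask_centres_mm[j]
            foci.append(Focus(float(x), float(y), float(z)))
        if not foci:  # an experiment must report at least one peak
            j = int(rng.integers(0, grid.n_voxels))
            x, y, z = grid.mask_centres_mm[j]
            foci.append(Focus(float(x), float(y), float(z)))
        experiments.append(Experiment(id=eid, n=int(sample_sizes[i]), foci=tuple(foci)))

    ds = Dataset(contrast_name=spec.contrast_name, experiments=tuple(experiments))
    gt = GroundTruth(planted_centres=tuple(map(tuple, centres)),
                     contributors=tuple(tuple(c) for c in contributors))
    return ds, gt


def add_planted_focus(ds: Dataset, centre: tuple[float, float, float],
                      experiment_ids: Sequence[str], grid: VoxelGrid,
                      jitter_sd_mm: float = 0.0, seed: int = 0) -> Dataset:
    """Append one focus near *centre* to each named experiment.

    Convenience for constructing datasets where a specific subset of
    experiments feeds a cluster (weak-signal and single-source scenarios).
    Jittered positions are snapped back into the mask if needed.
    """
    if not grid.mm_in_mask(np.asarray(centre, dtype=float)[None, :])[0]:
        raise ValueError(f"planted centre outside the mask: {centre}")
    rng = np.random.Generator(np.random.PCG64(seed))
    wanted = set(experiment_ids)
    missing = wanted - {e.id for e in ds.experiments}
    if missing:
        raise KeyError(f"unknown experiment ids: {sorted(missing)}")
    out = []
    for e in ds.experiments:
        if e.id in wanted:
            p = np.asarray(centre, dtype=float) + rng.normal(0.0, jitter_sd_mm, size=3)
            if not grid.mm_in_mask(p[None, :])[0]:
                p = grid.nearest_mask_centre(p)[0]
            e = Experiment(id=e.id, n=e.n,
                           foci=e.foci + (Focus(float(p[0]), float(p[1]), float(p[2])),))
        out.append(e)
    return Dataset(contrast_name=ds.contrast_name, experiments=tuple(out))


@dataclass(frozen=True)
class MacmSpec:
    """Generative settings for a synthetic MACM coordinate database.

    Each ``region_pairs`` entry is (A_centre, B_centre, coupling): an
    experiment emits a focus near A with probability ``p_primary`` and, when
    it did, also one near B with the pair's coupling probability.  The rest
    of each experiment's focus budget is uniform background.
    """

    n_experiments: int = 200
    region_pairs: tuple[tuple[tuple[float, float, float], tuple[float, float, float], float], ...] = ()
    p_primary: float = 0.3
    jitter_sd_mm: float = 5.0
    foci_per_experiment: int = 8
    sample_size_distribution: Callable[[np.random.Generator, int], np.ndarray] = default_sample_sizes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        for _, _, coupling in self.region_pairs:
            if not (0.0 <= coupling <= 1.0):
                raise ValueError("coupling probabilities must lie in [0, 1]")
        if not (0.0 <= self.p_primary <= 1.0):
            raise ValueError("p_primary must lie in [0, 1]")
        if self.foci_per_experiment < 1:
            raise ValueError("foci_per_experiment must be >= 1")


@dataclass(frozen=True)
class MacmGroundTruth:
    """Per region pair: which experiments emitted A, and which emitted B."""

    emitted_primary: tuple[tuple[str, ...], ...]
    emitted_coupled: tuple[tuple[str, ...], ...]


def generate_macm_db(spec: MacmSpec, grid: VoxelGrid) -> tuple[Dataset, MacmGroundTruth]:
    """Draw a synthetic coordinate database with seed-coupled structure."""
    for a, b, _ in spec.region_pairs:
        pts = np.array([a, b], dtype=float)
        if not grid.mm_in_mask(pts).all():
            raise ValueError(f"region centres outside the mask: {pts.tolist()}")

    rng = np.random.Generator(np.random.PCG64(spec.seed))
    sample_sizes = spec.sample_size_distribution(rng, spec.n_experiments)
    emitted_a: list[list[str]] = [[] for _ in spec.region_pairs]
    emitted_b: list[list[str]] = [[] for _ in spec.region_pairs]
    experiments: list[Experiment] = []

    def jittered(c: np.ndarray) -> Focus:
        p = np.asarray(c, dtype=float) + rng.normal(0.0, spec.jitter_sd_mm, size=3)
        if not grid.mm_in_mask(p[None, :])[0]:
            p = grid.nearest_mask_centre(p)[0]
        return Focus(float(p[0]), float(p[1]), float(p[2]))

    for i in range(spec.n_experiments):
        eid = f"db_{i + 1:04d}"
        foci: list[Focus] = []
        for pi, (a, b, coupling) in enumerate(spec.region_pairs):
            if rng.random() < spec.p_primary:
                foci.append(jittered(np.asarray(a)))
                emitted_a[pi].append(eid)
                if rng.random() < coupling:
                    foci.append(jittered(np.asarray(b)))
                    emitted_b[pi].append(eid)
        n_bg = max(spec.foci_per_experiment - len(foci), 1)
        for j in rng.integers(0, grid.n_voxels, size=n_bg):
            x, y, z = grid.mask_centres_mm[j]
            foci.append(Focus(float(x), float(y), float(z)))
        experiments.append(Experiment(id=eid, n=int(sample_sizes[i]), foci=tuple(foci)))

    gt = MacmGroundTruth(emitted_primary=tuple(tuple(v) for v in emitted_a),
                         emitted_coupled=tuple(tuple(v) for v in emitted_b))
    return Dataset(contrast_name="synthetic_macm_db", experiments=tuple(experiments)), gt


def write_ground_truth(gt: GroundTruth, stream: IO[str]) -> None:
    """TSV sidecar listing planted centres and contributing experiment ids."""
    gt.to_frame().to_csv(stream, sep="\t", index=False)
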