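"""Modelled-activation (MA) maps and the ALE statistic.

The MA map of one experiment assigns every voxel the probability that the
experiment's true activation lies there, combining the Gaussian kernels of
all its foci.  The ALE map treats experiments as independent evidence and
takes the probabilistic union across their MA maps:

    ALE(v) = 1 - prod_e (1 - MA_e(v))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import MNI, Experiment
from .grid import VoxelGrid
from .kernels import KernelConfig, fwhm_for_sample_size, fwhm_to_sigma

__all__ = ["MAMap", "ALEMap", "ma_map", "compute_ale", "paste_max", "paste_mul"]


@dataclass(frozen=True)
class MAMap:
    """One experiment's modelled-activation probability volume."""

    experiment_id: str
    data: np.ndarray  # full-grid volume, zero outside the mask
    grid: VoxelGrid


@dataclass(frozen=True)
class ALEMap:
    """The activation-likelihood volume of a dataset."""

    data: np.ndarray
    grid: VoxelGrid
    n_experiments: int


def ma_map(e: Experiment, grid: VoxelGrid, k: KernelConfig | None = None) -> MAMap:
    """Compute the MA map of one MNI-space experiment on the grid.

    Each focus contributes an isotropic Gaussian with FWHM set by the
    experiment's sample size, normalised so its discrete mass (density times
    voxel volume) is 1 up to the truncation tolerance; foci are combined per
    voxel by the configured rule.  Values outside the mask are zero.
    """
    if e.space != MNI:
        raise ValueError(f"experiment {e.id!r} must be in MNI space before analysis")
    if not e.foci:
        raise ValueError(f"experiment {e.id!r} has no foci")
    k = k or KernelConfig()
    fwhm = fwhm_for_sample_size(e.n, k)
    data = _accumulate_foci(np.array([f.as_tuple() for f in e.foci], dtype=float),
                            grid, fwhm, k)
    data[~grid.mask] = 0.0
    return MAMap(experiment_id=e.id, data=data, grid=grid)


def _accumulate_foci(xyz_mm: np.ndarray, grid: VoxelGrid, fwhm: float,
                     k: KernelConfig) -> np.ndarray:
    """Evaluate and combine the per-focus kernels at the voxel centres.

    Direct per-voxel evaluation at the exact (possibly off-centre) focus
    positions; the permutation engine uses the faster precomputed stamp,
    which agrees with this path when foci sit on voxel centres.
    """
    sigma = fwhm_to_sigma(fwhm)
    r_mm = k.truncation_factor * fwhm
    norm = grid.voxel_volume / ((2.0 * np.pi * sigma ** 2) ** 1.5)
    shape = np.array(grid.shape)
    vs = grid.voxel_size
    A = grid.affine[:3, :3]
    origin = grid.affine[:3, 3]

    if k.combine_rule == "max":
        out = np.zeros(grid.shape, dtype=float)
    else:
        out = np.ones(grid.shape, dtype=float)  # running prod(1 - p)

    for cx, cy, cz in xyz_mm:
        cvox = grid.mm_to_vox(np.array([cx, cy, cz]))
        lo = np.maximum(np.ceil(cvox - r_mm / vs).astype(int), 0)
        hi = np.minimum(np.floor(cvox + r_mm / vs).astype(int), shape - 1)
        if np.any(lo > hi):
            continue
        ii = np.arange(lo[0], hi[0] + 1)
        jj = np.arange(lo[1], hi[1] + 1)
        kk = np.arange(lo[2], hi[2] + 1)
        # mm offsets from the focus, axis-separated through the affine columns
        dx = (ii[:, None, None, None] * A[:, 0]
              + jj[None, :, None, None] * A[:, 1]
              + kk[None, None, :, None] * A[:, 2]
              + origin - np.array([cx, cy, cz]))
        d2 = (dx ** 2).sum(axis=-1)
        kern = norm * np.exp(-d2 / (2.0 * sigma ** 2))
        kern[d2 > r_mm ** 2] = 0.0
        sl = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        if k.combine_rule == "max":
            np.maximum(out[sl], kern, out=out[sl])
        else:
            out[sl] *= 1.0 - kern

    if k.combine_rule != "max":
        out = 1.0 - out
    return out


def compute_ale(ma_maps: Sequence[MAMap]) -> ALEMap:
    """Union of MA maps: ALE = 1 - prod(1 - MA).

    Maps are combined in experiment-id order so the result is bitwise
    invariant to the order in which the maps are supplied.
    """
    if not ma_maps:
        raise ValueError("compute_ale requires at least one MA map")
    grid = ma_maps[0].grid
    for m in ma_maps[1:]:
        if m.grid is not grid and not (
            m.grid.shape == grid.shape and np.array_equal(m.grid.affine, grid.affine)
            and np.array_equal(m.grid.mask, grid.mask)
        ):
            raise ValueError("all MA maps must share the same grid")
    if len(ma_maps) == 1:
        ale = ma_maps[0].data.copy()  # exact identity: 1 - (1 - x) may round
    else:
        prod = np.ones(grid.shape, dtype=float)
        for m in sorted(ma_maps, key=lambda m: m.experiment_id):
            prod *= 1.0 - m.data
        ale = 1.0 - prod
    ale[~grid.mask] = 0.0
    return ALEMap(data=ale, grid=grid, n_experiments=len(ma_maps))


def paste_max(target: np.ndarray, stamp: np.ndarray, centre_ijk: np.ndarray) -> None:
    """In-place voxelwise maximum of *stamp* centred at an integer voxel index.

    The stamp is clipped at the volume boundary.  Shared by the permutation
    engine; kept here next to the kernel semantics it implements.
    """
    tsl, ssl = _clipped_slices(target.shape, stamp.shape, centre_ijk)
    if tsl is not None:
        np.maximum(target[tsl], stamp[ssl], out=target[tsl])


def paste_mul(target: np.ndarray, one_minus_stamp: np.ndarray,
              centre_ijk: np.ndarray) -> None:
    """In-place multiply by (1 - kernel); running product for the union rule."""
    tsl, ssl = _clipped_slices(target.shape, one_minus_stamp.shape, centre_ijk)
    if tsl is not None:
        target[tsl] *= one_minus_stamp[ssl]


def _clipped_slices(target_shape, stamp_shape, centre_ijk):
    radii = (np.array(stamp_shape) - 1) // 2
    lo = centre_ijk - radii
    hi = centre_ijk + radii + 1
    tlo = np.maximum(lo, 0)
    thi = np.minimum(hi, target_shape)
    if np.any(tlo >= thi):
        return None, None
    slo = tlo - lo
    shi = np.array(stamp_shape) - (hi - thi)
    tsl = tuple(slice(a, b) for a, b in zip(tlo, thi))
    ssl = tuple(slice(a, b) for a, b in zip(slo, shi))
    return tsl, ssl
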