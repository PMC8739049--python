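"""The masked voxel grid every map lives on.

A :class:`VoxelGrid` pairs a boolean mask volume with a voxel->mm affine.
All public coordinates are MNI millimetres; voxel indices are 0-based and
internal.  The mask is a required input to the pipeline (supplied as NIfTI);
:func:`synthetic_brain_mask` builds an ellipsoidal stand-in of brain-like
extent for simulation and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import nibabel as nib
import numpy as np
from scipy.spatial import cKDTree

from .datasets import Dataset

__all__ = ["VoxelGrid", "make_grid", "synthetic_brain_mask", "foci_outside_mask"]


@dataclass(frozen=True)
class VoxelGrid:
    """Boolean analysis mask plus its voxel->mm affine."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        affine = np.asarray(self.affine, dtype=float)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if not mask.any():
            raise ValueError("mask is empty: no in-mask voxels")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @cached_property
    def voxel_size(self) -> np.ndarray:
        """Length of each voxel edge in mm (per axis)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @cached_property
    def mask_indices(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel indices of the in-mask voxels."""
        return np.argwhere(self.mask)

    @cached_property
    def flat_mask_index(self) -> np.ndarray:
        """Raveled positions of the in-mask voxels, for scatter/gather."""
        return np.flatnonzero(self.mask.ravel())

    def vox_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_vox(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) mm coordinates to fractional voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def mm_in_mask(self, xyz: np.ndarray) -> np.ndarray:
        """Boolean array: does each mm coordinate fall in an in-mask voxel?"""
        ijk = np.rint(self.mm_to_vox(xyz)).astype(int)
        ijk = np.atleast_2d(ijk)
        ok = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=-1)
        out = np.zeros(len(ijk), dtype=bool)
        out[ok] = self.mask[tuple(ijk[ok].T)]
        return out

    @cached_property
    def mask_centres_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of the in-mask voxel centres."""
        return self.vox_to_mm(self.mask_indices)

    @cached_property
    def _centre_tree(self) -> cKDTree:
        return cKDTree(self.mask_centres_mm)

    def nearest_mask_centre(self, xyz: np.ndarray) -> np.ndarray:
        """Snap (..., 3) mm points to the nearest in-mask voxel centre."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        _, idx = self._centre_tree.query(xyz)
        return self.mask_centres_mm[idx]

    def scatter(self, in_mask_values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Expand a vector over in-mask voxels into a full 3-D volume."""
        out = np.full(self.mask.size, fill, dtype=in_mask_values.dtype)
        out[self.flat_mask_index] = in_mask_values
        return out.reshape(self.shape)

    def gather(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask values of a full 3-D volume."""
        return volume.ravel()[self.flat_mask_index]

    def to_image(self, volume: np.ndarray) -> nib.Nifti1Image:
        """Wrap a full 3-D volume as a NIfTI image with this grid's affine."""
        return nib.Nifti1Image(np.asarray(volume), self.affine)


def make_grid(mask_volume: nib.Nifti1Image | str, voxel_size: float | None = None) -> VoxelGrid:
    """Build the analysis grid from a NIfTI brain mask.

    If *voxel_size* differs from the mask's native resolution the mask is
    resampled by nearest neighbour onto an axis-aligned grid of that
    isotropic resolution covering the same field of view.
    """
    img = nib.load(mask_volume) if isinstance(mask_volume, str) else mask_volume
    data = np.asarray(img.dataobj)
    mask = data > 0.5
    affine = np.asarray(img.affine, dtype=float)
    if not mask.any():
        raise ValueError("mask volume contains no nonzero voxels")

    native = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if voxel_size is not None and not np.allclose(native, voxel_size):
        mask, affine = _resample_nearest(mask, affine, float(voxel_size))
        if not mask.any():
            raise ValueError("mask is empty after resampling")
    return VoxelGrid(mask=mask, affine=affine)


def _resample_nearest(mask: np.ndarray, affine: np.ndarray, voxel_size: float):
    """Nearest-neighbour resampling onto an axis-aligned isotropic grid."""
    # mm bounding box of the source voxel centres
    corners_ijk = np.array([[i, j, k] for i in (0, mask.shape[0] - 1)
                            for j in (0, mask.shape[1] - 1)
                            for k in (0, mask.shape[2] - 1)], dtype=float)
    corners_mm = corners_ijk @ affine[:3, :3].T + affine[:3, 3]
    lo, hi = corners_mm.min(axis=0), corners_mm.max(axis=0)
    shape = np.maximum(np.floor((hi - lo) / voxel_size).astype(int) + 1, 1)
    new_affine = np.eye(4)
    new_affine[:3, :3] *= voxel_size
    new_affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    mm = ijk @ new_affine[:3, :3].T + new_affine[:3, 3]
    src = np.rint(mm @ np.linalg.inv(affine)[:3, :3].T + np.linalg.inv(affine)[:3, 3]).astype(int)
    ok = np.all((src >= 0) & (src < np.array(mask.shape)), axis=1)
    out = np.zeros(len(ijk), dtype=bool)
    out[ok] = mask[tuple(src[ok].T)]
    return out.reshape(tuple(shape)), new_affine


def synthetic_brain_mask(voxel_size: float = 2.0,
                         semi_axes_mm: tuple[float, float, float] = (70.0, 85.0, 70.0),
                         ) -> nib.Nifti1Image:
    """An ellipsoidal synthetic brain mask of adult-brain extent.

    Centred on the MNI origin with RAS+ axes; default semi-axes give a
    volume of about 1.7 litres at the cerebrum-plus-cerebellum scale.  This
    is a geometric stand-in for a tissue mask, intended for simulation.
    """
    a, b, c = semi_axes_mm
    half = np.array([a, b, c])
    shape = (np.ceil(2 * half / voxel_size).astype(int) + 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -(shape - 1) / 2.0 * voxel_size
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    mm = (np.stack([ii, jj, kk], axis=-1) * voxel_size) + affine[:3, 3]
    r2 = (mm[..., 0] / a) ** 2 + (mm[..., 1] / b) ** 2 + (mm[..., 2] / c) ** 2
    mask = (r2 <= 1.0).astype(np.uint8)
    return nib.Nifti1Image(mask, affine)


def foci_outside_mask(ds: Dataset, grid: VoxelGrid) -> list[tuple[str, tuple[float, float, float]]]:
    """List (experiment id, focus) pairs whose focus misses the mask.

    Such foci are retained in the dataset — their kernels still contribute
    wherever the mask is true — but a warning names them so that data-entry
    errors are not silently absorbed.
    """
    out = []
    for e in ds.experiments:
        xyz = np.array([f.as_tuple() for f in e.foci])
        inside = grid.mm_in_mask(xyz)
        for f, ok in zip(e.foci, inside):
            if not ok:
                out.append((e.id, f.as_tuple()))
    if out:
        warnings.warn(f"{len(out)} foci fall outside the analysis mask: "
                      f"{out[:5]}{' ...' if len(out) > 5 else ''}", stacklevel=2)
    return out
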