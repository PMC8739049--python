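"""Reference-space handling: Talairach <-> MNI affine conversion.

Foci reported in Talairach space are mapped into MNI space with the inverse
of the bundled icbm2tal affine (Lancaster-style pooled transform), the same
conversion convention used by the GingerALE "convert foci" tool.  All
downstream analysis operates in MNI millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import icbm2tal_matrix
from .datasets import MNI, TAL, Dataset, Experiment, Focus

__all__ = ["SpaceTransform", "default_transform", "tal_to_mni", "mni_to_tal",
           "dataset_to_mni"]


@dataclass(frozen=True)
class SpaceTransform:
    """An invertible 4x4 affine mapping Talairach mm to MNI mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of mm coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def apply_inverse(self, xyz: np.ndarray) -> np.ndarray:
        inv = self.inverse
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def default_transform() -> SpaceTransform:
    """Talairach->MNI transform from the bundled icbm2tal constants.

    The constants file stores the MNI->Talairach direction as published;
    its inverse is the conversion applied to Talairach-space foci.
    """
    return SpaceTransform(matrix=np.linalg.inv(icbm2tal_matrix()))


def tal_to_mni(focus: Focus, t: SpaceTransform | None = None) -> Focus:
    """Convert one Talairach focus into MNI space.

    An MNI-space input is returned unchanged with a warning (idempotence).
    """
    if focus.space == MNI:
        warnings.warn(f"focus {focus.as_tuple()} is already in MNI space; no-op",
                      stacklevel=2)
        return focus
    t = t or default_transform()
    x, y, z = t.apply(np.array(focus.as_tuple()))
    return Focus(float(x), float(y), float(z), space=MNI)


def mni_to_tal(focus: Focus, t: SpaceTransform | None = None) -> Focus:
    """Inverse conversion, mainly for round-trip checks."""
    if focus.space == TAL:
        warnings.warn(f"focus {focus.as_tuple()} is already in Talairach space; no-op",
                      stacklevel=2)
        return focus
    t = t or default_transform()
    x, y, z = t.apply_inverse(np.array(focus.as_tuple()))
    return Focus(float(x), float(y), float(z), space=TAL)


def dataset_to_mni(ds: Dataset, t: SpaceTransform | None = None) -> Dataset:
    """Return a copy of *ds* with every Talairach experiment converted to MNI."""
    t = t or default_transform()
    out = []
    for e in ds.experiments:
        if e.space == MNI:
            out.append(e)
            continue
        xyz = t.apply(np.array([f.as_tuple() for f in e.foci]))
        foci = tuple(Focus(float(x), float(y), float(z), space=MNI) for x, y, z in xyz)
        out.append(Experiment(id=e.id, n=e.n, foci=foci, space=MNI))
    return Dataset(contrast_name=ds.contrast_name, experiments=tuple(out))
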