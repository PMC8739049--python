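"""Sample-size-dependent Gaussian kernels for modelled-activation maps.

Each focus is modelled as an isotropic 3-D Gaussian whose width reflects two
sources of spatial uncertainty: between-subject anatomical variability
(which averages out with the square root of the sample size) and
between-template registration differences (which do not).  The per-experiment
FWHM is therefore

    FWHM(n) = sqrt(fwhm_subject^2 / n + fwhm_template^2)

so larger studies get tighter, taller kernels and carry more weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import default_kernel_fwhms

__all__ = ["KernelConfig", "fwhm_for_sample_size", "fwhm_to_sigma", "kernel_stamp"]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class KernelConfig:
    """Kernel calibration constants and the within-experiment combine rule.

    combine_rule 'max' takes, at each voxel, the largest single-focus
    probability of the experiment (the modified ALE that stops multiple
    nearby foci of one experiment from stacking); 'union' combines them as
    independent probabilities, 1 - prod(1 - p).
    """

    fwhm_subject_mm: float | None = None
    fwhm_template_mm: float | None = None
    combine_rule: str = "max"
    truncation_factor: float = 3.0  # kernel support radius, in multiples of FWHM

    def __post_init__(self) -> None:
        subj, tmpl = default_kernel_fwhms()
        if self.fwhm_subject_mm is None:
            object.__setattr__(self, "fwhm_subject_mm", subj)
        if self.fwhm_template_mm is None:
            object.__setattr__(self, "fwhm_template_mm", tmpl)
        if self.fwhm_subject_mm <= 0 or self.fwhm_template_mm <= 0:
            raise ValueError("kernel FWHMs must be positive")
        if self.combine_rule not in ("max", "union"):
            raise ValueError(f"combine_rule must be 'max' or 'union', got {self.combine_rule!r}")
        if self.truncation_factor <= 0:
            raise ValueError("truncation_factor must be positive")


def fwhm_for_sample_size(n: int, k: KernelConfig | None = None) -> float:
    """Kernel FWHM in mm for an experiment of sample size *n*.

    Strictly decreasing in n, bounded below by the template FWHM.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    k = k or KernelConfig()
    return float(np.sqrt(k.fwhm_subject_mm ** 2 / n + k.fwhm_template_mm ** 2))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given FWHM (FWHM = sigma * sqrt(8 ln 2))."""
    return fwhm_mm * _FWHM_TO_SIGMA


@lru_cache(maxsize=64)
def kernel_stamp(fwhm_mm: float, voxel_size: tuple[float, float, float],
                 voxel_volume: float, truncation_factor: float = 3.0) -> np.ndarray:
    """Discrete kernel centred on a voxel centre, as a (2R+1)^3-style block.

    Values are Gaussian density times voxel volume, so the block sums to ~1
    (analytic normalisation; the truncation at ``truncation_factor * FWHM``
    loses negligible mass).  Used by the permutation engine, where null foci
    sit exactly on voxel centres and the same block can be pasted anywhere.
    """
    sigma = fwhm_to_sigma(fwhm_mm)
    r_mm = truncation_factor * fwhm_mm
    vs = np.asarray(voxel_size, dtype=float)
    radii = np.ceil(r_mm / vs).astype(int)
    axes = [np.arange(-r, r + 1) * s for r, s in zip(radii, vs)]
    d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
          + axes[2][None, None, :] ** 2)
    norm = voxel_volume / ((2.0 * np.pi * sigma ** 2) ** 1.5)
    stamp = norm * np.exp(-d2 / (2.0 * sigma ** 2))
    stamp[d2 > r_mm ** 2] = 0.0
    return stamp
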