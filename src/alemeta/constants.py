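"""Load the versioned numeric constants bundled with the package.

The kernel calibration and the Talairach/MNI affine are literature-derived
numbers that the rest of the code must never hard-code; they live in
``data/constants.json`` so that a reviewer can audit (and a user can
override) them in one place.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "load_constants",
    "constants_checksum",
    "default_kernel_fwhms",
    "icbm2tal_matrix",
]


def _constants_bytes() -> bytes:
    ref = resources.files("alemeta") / "data" / "constants.json"
    return ref.read_bytes()


@lru_cache(maxsize=1)
def load_constants() -> dict:
    """Return the parsed constants file as a dict."""
    return json.loads(_constants_bytes().decode("utf-8"))


def constants_checksum() -> str:
    """SHA-256 of the constants file, recorded in run manifests."""
    return hashlib.sha256(_constants_bytes()).hexdigest()


def default_kernel_fwhms() -> tuple[float, float]:
    """(fwhm_subject_mm, fwhm_template_mm) from the bundled calibration."""
    k = load_constants()["ale_kernel"]
    return float(k["fwhm_subject_mm"]), float(k["fwhm_template_mm"])


def icbm2tal_matrix() -> np.ndarray:
    """The 4x4 MNI->Talairach affine (the bundled icbm2tal constants)."""
    m = np.asarray(load_constants()["icbm2tal"]["mni_to_tal"], dtype=float)
    if m.shape != (4, 4):
        raise ValueError("icbm2tal matrix in constants file must be 4x4")
    return m
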