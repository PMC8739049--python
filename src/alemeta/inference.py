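"""Permutation inference for ALE maps.

The null hypothesis is spatial non-convergence: each permutation redraws
every experiment's foci uniformly over the in-mask voxel centres (keeping
its focus count and sample size, hence its kernel), and recomputes the ALE
map.  Pooling the resulting ALE values over voxels and permutations gives
the voxel-level empirical null; the largest suprathreshold cluster of each
permutation gives the max-cluster-size distribution used for cluster-level
family-wise error control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ale import ALEMap, compute_ale, ma_map, paste_max, paste_mul
from .datasets import Dataset
from .grid import VoxelGrid, foci_outside_mask
from .kernels import KernelConfig, fwhm_for_sample_size, kernel_stamp

__all__ = [
    "InferenceConfig", "NullDistribution", "ClusterTable", "AnalysisResult",
    "PermutationEngine", "build_null", "voxel_p", "label_clusters",
    "threshold_and_correct", "run_ale_analysis",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

TABLE_COLUMNS = ["cluster_no", "volume_mm3", "x", "y", "z", "max_ale",
                 "p_cluster_fwe", "corrected_flag"]


@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds and permutation settings for the corrected analysis."""

    p_voxel: float = 0.001          # cluster-forming (voxel-level) threshold
    p_fwe: float = 0.05             # cluster-level family-wise error threshold
    n_perm: int = 1000              # permutations for the empirical null
    extent_mm3: float = 300.0       # minimum cluster volume reported
    connectivity: int = 26          # 6, 18 or 26 neighbours
    seed: int = 0
    null_samples_cap: int = 20_000_000   # pooled voxel-null subsample ceiling
    max_store_bytes: int = 512 * 1024 * 1024  # per-permutation map cache limit

    def __post_init__(self) -> None:
        if not (0.0 < self.p_voxel < 1.0 and 0.0 < self.p_fwe < 1.0):
            raise ValueError("p_voxel and p_fwe must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm below 100 gives an unstable null tail")
        if self.extent_mm3 < 0:
            raise ValueError("extent_mm3 must be non-negative")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class NullDistribution:
    """Empirical null: pooled voxel ALE values and per-permutation max cluster sizes."""

    voxel_ale_samples: np.ndarray   # sorted ascending, pooled over voxels & perms
    max_cluster_sizes: np.ndarray   # one voxel count per permutation
    ale_cutoff: float               # ALE value above which voxel p < p_voxel
    n_perm: int
    p_voxel: float

    @property
    def n_samples(self) -> int:
        return len(self.voxel_ale_samples)


@dataclass(frozen=True)
class ClusterTable:
    """Significant-cluster report (volume, peak, max ALE, cluster-FWE p).

    ``corrected`` is False when nothing survived FWE correction and the
    table instead lists the uncorrected (voxel p < p_voxel, extent-filtered)
    clusters — the conventional fallback report.
    """

    rows: pd.DataFrame
    corrected: bool

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def empty(self) -> bool:
        return self.rows.empty

    def to_tsv(self, path) -> None:
        df = self.rows.copy()
        for col in ("max_ale", "p_cluster_fwe"):
            df[col] = df[col].map(lambda v: f"{v:.8f}")
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the corrected analysis of one contrast produces."""

    dataset: Dataset
    ale: ALEMap
    p_values: np.ndarray            # full volume of voxel-level p (1 outside mask)
    null: NullDistribution
    table: ClusterTable
    cluster_labels: np.ndarray      # int volume; row k of table <-> label k
    config: InferenceConfig
    kernel: KernelConfig

    @property
    def corrected_mask(self) -> np.ndarray:
        """Boolean volume of corrected-significant voxels (empty if fallback)."""
        if not self.table.corrected or self.table.empty:
            return np.zeros(self.ale.grid.shape, dtype=bool)
        return self.cluster_labels > 0


class PermutationEngine:
    """Fast ALE evaluation for foci placed on in-mask voxel centres.

    Precomputes one discrete kernel block per experiment (keyed by its
    sample-size-dependent FWHM) and pastes it at integer voxel positions,
    which is exact for null foci drawn on the voxel-centre lattice.
    """

    def __init__(self, ds: Dataset, grid: VoxelGrid, k: KernelConfig | None = None):
        self.grid = grid
        self.kernel = k = k or KernelConfig()
        vs = tuple(np.round(grid.voxel_size, 9))
        self.experiments = [(e.id, e.n_foci, e.n) for e in ds.experiments]
        self._stamps = [
            kernel_stamp(round(fwhm_for_sample_size(e.n, k), 9), vs,
                         grid.voxel_volume, k.truncation_factor)
            for e in ds.experiments
        ]
        self._one_minus = ([1.0 - s for s in self._stamps]
                           if k.combine_rule == "union" else None)
        self.n_foci_total = sum(nf for _, nf, _ in self.experiments)

    def draw_foci(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform draw of all experiments' foci over in-mask voxels (flat index)."""
        return rng.integers(0, self.grid.n_voxels, size=self.n_foci_total)

    def ale_from_indices(self, flat_idx: np.ndarray) -> np.ndarray:
        """ALE volume for one permutation's foci (in-mask voxel positions)."""
        grid = self.grid
        union = self.kernel.combine_rule == "union"
        prod = np.ones(grid.shape, dtype=float)
        ma = np.empty(grid.shape, dtype=float)
        pos = 0
        centres = grid.mask_indices
        for e_idx, ((_, nf, _), stamp) in enumerate(zip(self.experiments, self._stamps)):
            if union:
                ma.fill(1.0)  # running prod(1 - kernel)
                for i in flat_idx[pos:pos + nf]:
                    paste_mul(ma, self._one_minus[e_idx], centres[i])
                prod *= ma
            else:
                ma.fill(0.0)
                for i in flat_idx[pos:pos + nf]:
                    paste_max(ma, stamp, centres[i])
                prod *= 1.0 - ma
            pos += nf
        ale = 1.0 - prod
        ale[~grid.mask] = 0.0
        return ale


def _max_exceedances(alpha: float, n: int) -> int:
    """Largest integer g with (1 + g) / (1 + n) < alpha."""
    t = alpha * (1 + n) - 1
    g = math.floor(t)
    if g == t:  # boundary: strict inequality
        g -= 1
    return g


def build_null(ds: Dataset, grid: VoxelGrid, k: KernelConfig | None,
               cfg: InferenceConfig) -> NullDistribution:
    """Run the permutation test and assemble the empirical null.

    Deterministic given ``cfg.seed``.  Per-permutation ALE maps are cached
    in float32 when they fit under ``cfg.max_store_bytes``; otherwise they
    are recomputed from the (tiny) cached foci draws for the cluster pass.
    """
    k = k or KernelConfig()
    engine = PermutationEngine(ds, grid, k)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    n_mask = grid.n_voxels

    draws = [engine.draw_foci(rng) for _ in range(cfg.n_perm)]

    store = cfg.n_perm * n_mask * 4 <= cfg.max_store_bytes
    cache = np.empty((cfg.n_perm, n_mask), dtype=np.float32) if store else None

    per_perm = min(n_mask, max(1, cfg.null_samples_cap // cfg.n_perm))
    pooled = np.empty(cfg.n_perm * per_perm, dtype=np.float64)
    for p, flat_idx in enumerate(draws):
        ale = engine.ale_from_indices(flat_idx)
        vals = grid.gather(ale)
        if store:
            cache[p] = vals
        if per_perm == n_mask:
            sample = vals
        else:
            sample = vals[rng.integers(0, n_mask, size=per_perm)]
        pooled[p * per_perm:(p + 1) * per_perm] = sample

    pooled.sort()
    g_max = _max_exceedances(cfg.p_voxel, len(pooled))
    if g_max < 0:
        cutoff = np.inf  # p_voxel unattainable at this null size
    else:
        cutoff = float(pooled[len(pooled) - 1 - g_max])

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[cfg.connectivity])
    max_sizes = np.zeros(cfg.n_perm, dtype=np.int64)
    binary = np.zeros(grid.shape, dtype=bool)
    for p in range(cfg.n_perm):
        if store:
            vals = cache[p].astype(np.float64)
        else:
            vals = grid.gather(engine.ale_from_indices(draws[p]))
        binary.ravel()[grid.flat_mask_index] = vals > cutoff
        if binary.any():
            labels, n_lab = ndimage.label(binary, structure=structure)
            if n_lab:
                max_sizes[p] = np.bincount(labels.ravel())[1:].max()
        binary[:] = False

    return NullDistribution(voxel_ale_samples=pooled, max_cluster_sizes=max_sizes,
                            ale_cutoff=cutoff, n_perm=cfg.n_perm, p_voxel=cfg.p_voxel)


def voxel_p(ale: ALEMap, null: NullDistribution) -> np.ndarray:
    """Voxel-level permutation p-map with add-one smoothing.

    p(v) = (1 + #{null samples >= ALE(v)}) / (1 + N); outside the mask p = 1.
    """
    grid = ale.grid
    vals = grid.gather(ale.data)
    n = null.n_samples
    greater_equal = n - np.searchsorted(null.voxel_ale_samples, vals, side="left")
    p = (1.0 + greater_equal) / (1.0 + n)
    out = np.ones(grid.shape, dtype=float)
    out.ravel()[grid.flat_mask_index] = p
    return out


def label_clusters(binary_map: np.ndarray, grid: VoxelGrid, connectivity: int = 26,
                   values: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Connected components of a binary volume, with volume and peak geometry.

    Returns (table, labels).  ``values`` (usually the ALE map) defines each
    cluster's peak; without it peaks are the first voxel in scan order.
    Rows are sorted by volume descending and labels renumbered to match.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n_lab = ndimage.label(np.asarray(binary_map, dtype=bool), structure=structure)
    rows = []
    for lab in range(1, n_lab + 1):
        voxels = np.argwhere(labels == lab)
        size = len(voxels)
        if values is not None:
            vals = values[tuple(voxels.T)]
            peak_ijk = voxels[int(np.argmax(vals))]
            max_val = float(vals.max())
        else:
            peak_ijk = voxels[0]
            max_val = float("nan")
        peak_mm = grid.vox_to_mm(peak_ijk)
        rows.append({"label": lab, "size_vox": size,
                     "volume_mm3": size * grid.voxel_volume,
                     "x": float(peak_mm[0]), "y": float(peak_mm[1]),
                     "z": float(peak_mm[2]), "max_ale": max_val})
    df = pd.DataFrame(rows, columns=["label", "size_vox", "volume_mm3",
                                     "x", "y", "z", "max_ale"])
    if not df.empty:
        df = df.sort_values(["volume_mm3", "max_ale"], ascending=[False, False],
                            kind="mergesort").reset_index(drop=True)
        remap = np.zeros(n_lab + 1, dtype=labels.dtype)
        for new, old in enumerate(df["label"], start=1):
            remap[old] = new
        labels = remap[labels]
        df["label"] = np.arange(1, len(df) + 1)
    return df, labels


def threshold_and_correct(ale: ALEMap, p_map: np.ndarray, null: NullDistribution,
                          cfg: InferenceConfig) -> tuple[ClusterTable, np.ndarray]:
    """Cluster-forming threshold, cluster-level FWE and extent filter.

    Clusters surviving both the FWE threshold and the extent filter are
    reported with ``corrected_flag=True``.  When none survive, the
    uncorrected suprathreshold clusters (extent-filtered) are reported with
    ``corrected_flag=False`` instead, so a convergence tendency is still
    visible in the output.

    Returns (table, labels volume aligned with the table's cluster numbers).
    """
    grid = ale.grid
    binary = (p_map < cfg.p_voxel) & grid.mask
    geometry, labels = label_clusters(binary, grid, cfg.connectivity, values=ale.data)
    if geometry.empty:
        empty = pd.DataFrame(columns=TABLE_COLUMNS)
        return ClusterTable(rows=empty, corrected=False), labels

    sizes = geometry["size_vox"].to_numpy()
    exceed = (null.max_cluster_sizes[None, :] >= sizes[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (1.0 + null.n_perm)
    geometry = geometry.assign(p_cluster_fwe=p_fwe)

    keep = (p_fwe < cfg.p_fwe) & (geometry["volume_mm3"].to_numpy() >= cfg.extent_mm3)
    corrected = bool(keep.any())
    if not corrected:
        keep = geometry["volume_mm3"].to_numpy() >= cfg.extent_mm3
    selected = geometry.loc[keep].reset_index(drop=True)

    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    for new, old in enumerate(selected["label"], start=1):
        remap[old] = new
    labels = remap[labels]

    table = pd.DataFrame({
        "cluster_no": np.arange(1, len(selected) + 1),
        "volume_mm3": selected["volume_mm3"],
        "x": selected["x"], "y": selected["y"], "z": selected["z"],
        "max_ale": selected["max_ale"],
        "p_cluster_fwe": selected["p_cluster_fwe"],
        "corrected_flag": corrected,
    }, columns=TABLE_COLUMNS)
    return ClusterTable(rows=table, corrected=corrected), labels


def run_ale_analysis(ds: Dataset, grid: VoxelGrid, k: KernelConfig | None = None,
                     cfg: InferenceConfig | None = None,
                     warn_outside: bool = True) -> AnalysisResult:
    """The full corrected analysis of one contrast.

    MA maps -> ALE -> permutation null -> voxel p -> cluster-FWE table.
    """
    k = k or KernelConfig()
    cfg = cfg or InferenceConfig()
    if warn_outside:
        foci_outside_mask(ds, grid)
    ma_maps = [ma_map(e, grid, k) for e in ds.experiments]
    ale = compute_ale(ma_maps)
    null = build_null(ds, grid, k, cfg)
    p_map = voxel_p(ale, null)
    table, labels = threshold_and_correct(ale, p_map, null, cfg)
    return AnalysisResult(dataset=ds, ale=ale, p_values=p_map, null=null,
                          table=table, cluster_labels=labels, config=cfg, kernel=k)
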