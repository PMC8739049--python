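"""Robustness checks on a corrected ALE result.

Two complementary procedures:

* **Jackknife** — repeat the corrected analysis leaving out one experiment
  at a time; a cluster that only replicates when a particular study is
  present is driven by that study.
* **Fail-safe-N noise injection** — append synthetic "unpublished" null
  experiments (drawn from the dataset's own focus-count and sample-size
  distributions, foci uniform over the mask) at increasing rates and
  re-test; the highest rate a cluster withstands bounds its fail-safe N,
  reported as a band over the rate grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .datasets import Dataset, Experiment, Focus
from .grid import VoxelGrid
from .inference import AnalysisResult, InferenceConfig, run_ale_analysis
from .kernels import KernelConfig

__all__ = ["JackknifeResult", "FSNResult", "jackknife", "inject_noise",
           "fail_safe_n", "DEFAULT_FSN_RATES"]

DEFAULT_FSN_RATES = (0.06, 0.10, 0.20, 0.30)


@dataclass(frozen=True)
class JackknifeResult:
    """Per-cluster replication counts over the leave-one-out runs."""

    cluster_no: tuple[int, ...]
    replicate_count: tuple[int, ...]
    total_runs: int
    replicated_in: dict[int, tuple[str, ...]]  # cluster_no -> ids of runs' excluded exp where it replicated

    def as_fraction(self) -> dict[int, float]:
        return {c: r / self.total_runs
                for c, r in zip(self.cluster_no, self.replicate_count)}


@dataclass(frozen=True)
class FSNResult:
    """Per-cluster fail-safe-N bands over the tested noise-rate grid."""

    cluster_no: tuple[int, ...]
    rates: tuple[float, ...]
    survival_fraction: dict[int, tuple[float, ...]]  # cluster -> fraction per rate
    band: dict[int, str]                             # cluster -> e.g. ">30%"
    n_realizations: int


def _seed_stream(seed: int, n: int) -> list[int]:
    """n reproducible child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


def _overlaps(cluster_voxels: np.ndarray, significant: np.ndarray) -> bool:
    """>= 1 voxel shared between an original cluster and a run's corrected map."""
    return bool(significant[cluster_voxels].any())


def jackknife(ds: Dataset, grid: VoxelGrid, k: KernelConfig | None = None,
              cfg: InferenceConfig | None = None,
              baseline: AnalysisResult | None = None) -> JackknifeResult:
    """Leave-one-experiment-out replication of every corrected cluster.

    A cluster replicates in a run when the run's corrected-significant map
    shares at least one voxel with it.  Runs whose own corrected table is
    empty (fallback) replicate nothing.
    """
    if ds.n_experiments < 2:
        raise ValueError("jackknife requires at least 2 experiments")
    k = k or KernelConfig()
    cfg = cfg or InferenceConfig()
    if baseline is None:
        baseline = run_ale_analysis(ds, grid, k, cfg, warn_outside=False)
    if not baseline.table.corrected or baseline.table.empty:
        raise ValueError("jackknife needs at least one corrected-significant cluster")

    cluster_nos = tuple(int(c) for c in baseline.table.rows["cluster_no"])
    cluster_voxels = {c: baseline.cluster_labels == c for c in cluster_nos}

    counts = dict.fromkeys(cluster_nos, 0)
    replicated_in: dict[int, list[str]] = {c: [] for c in cluster_nos}
    seeds = _seed_stream(cfg.seed, ds.n_experiments)
    for excluded, run_seed in zip(ds.experiments, seeds):
        sub = ds.without(excluded.id)
        res = run_ale_analysis(sub, grid, k, replace(cfg, seed=run_seed),
                               warn_outside=False)
        sig = res.corrected_mask
        for c in cluster_nos:
            if _overlaps(cluster_voxels[c], sig):
                counts[c] += 1
                replicated_in[c].append(excluded.id)

    return JackknifeResult(
        cluster_no=cluster_nos,
        replicate_count=tuple(counts[c] for c in cluster_nos),
        total_runs=ds.n_experiments,
        replicated_in={c: tuple(v) for c, v in replicated_in.items()},
    )


def inject_noise(ds: Dataset, rate: float, seed: int, grid: VoxelGrid) -> Dataset:
    """Append ceil(rate * E) synthetic null experiments to the dataset.

    Each injected experiment draws its focus count and sample size (with
    replacement) from the dataset's own empirical distributions and places
    its foci uniformly over the in-mask voxel centres.  The original
    experiments are untouched.
    """
    if rate <= 0:
        raise ValueError(f"noise rate must be positive, got {rate}")
    if rate > 1:
        raise ValueError(f"noise rate above 1 is not meaningful, got {rate}")
    rng = np.random.Generator(np.random.PCG64(seed))
    m = math.ceil(rate * ds.n_experiments)
    foci_counts = np.array([e.n_foci for e in ds.experiments])
    sample_sizes = np.array([e.n for e in ds.experiments])
    noise = []
    for j in range(m):
        nf = int(rng.choice(foci_counts))
        n = int(rng.choice(sample_sizes))
        idx = rng.integers(0, grid.n_voxels, size=nf)
        foci = tuple(Focus(*grid.mask_centres_mm[i]) for i in idx)
        noise.append(Experiment(id=f"__noise_{j + 1:03d}", n=n, foci=foci))
    return Dataset(contrast_name=ds.contrast_name,
                   experiments=ds.experiments + tuple(noise))


def fail_safe_n(ds: Dataset, grid: VoxelGrid, k: KernelConfig | None = None,
                cfg: InferenceConfig | None = None,
                rates: tuple[float, ...] = DEFAULT_FSN_RATES,
                n_realizations: int = 10,
                baseline: AnalysisResult | None = None) -> FSNResult:
    """Noise-injection robustness bands for every corrected cluster.

    For each rate, ``n_realizations`` noisy datasets are analysed; a cluster
    *survives* the rate if it overlaps a corrected-significant cluster in at
    least half of them.  The reported band brackets the highest surviving
    rate (e.g. ">30%" when the top rate survives, "20%>FSN>10%" when 10%
    survives but 20% does not).
    """
    if not rates:
        raise ValueError("rates must be a non-empty ascending grid")
    if list(rates) != sorted(rates):
        raise ValueError("rates must be ascending")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    k = k or KernelConfig()
    cfg = cfg or InferenceConfig()
    if baseline is None:
        baseline = run_ale_analysis(ds, grid, k, cfg, warn_outside=False)
    if not baseline.table.corrected or baseline.table.empty:
        raise ValueError("fail-safe-N needs at least one corrected-significant "
                         "cluster in the baseline analysis")

    cluster_nos = tuple(int(c) for c in baseline.table.rows["cluster_no"])
    cluster_voxels = {c: baseline.cluster_labels == c for c in cluster_nos}

    seeds = _seed_stream(cfg.seed + 1, len(rates) * n_realizations * 2)
    survival: dict[int, list[float]] = {c: [] for c in cluster_nos}
    si = iter(seeds)
    for rate in rates:
        hits = dict.fromkeys(cluster_nos, 0)
        for _ in range(n_realizations):
            noisy = inject_noise(ds, rate, next(si), grid)
            res = run_ale_analysis(noisy, grid, k, replace(cfg, seed=next(si)),
                                   warn_outside=False)
            sig = res.corrected_mask
            for c in cluster_nos:
                if _overlaps(cluster_voxels[c], sig):
                    hits[c] += 1
        for c in cluster_nos:
            survival[c].append(hits[c] / n_realizations)

    bands = {c: _band_label(rates, survival[c]) for c in cluster_nos}
    return FSNResult(cluster_no=cluster_nos, rates=tuple(rates),
                     survival_fraction={c: tuple(v) for c, v in survival.items()},
                     band=bands, n_realizations=n_realizations)


def _band_label(rates: tuple[float, ...], fractions: list[float]) -> str:
    """Band between the highest surviving rate and the next rate up."""
    pct = [round(r * 100) for r in rates]
    surviving = [i for i, f in enumerate(fractions) if f >= 0.5]
    if not surviving:
        return f"<{pct[0]}%"
    top = max(surviving)
    if top == len(rates) - 1:
        return f">{pct[-1]}%"
    return f"{pct[top + 1]}%>FSN>{pct[top]}%"
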