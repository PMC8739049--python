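"""End-to-end orchestration of contrasts: load -> convert -> ALE ->
inference -> robustness -> MACM, with reproducible file outputs.

A contrast with fewer experiments than ``min_experiments`` is refused with
an explanatory report rather than analysed: convergence over two or three
experiments is not meta-analytic evidence, so no maps are emitted for it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import constants_checksum
from .datasets import Dataset, read_sleuth
from .grid import VoxelGrid, make_grid
from .inference import AnalysisResult, InferenceConfig, run_ale_analysis
from .kernels import KernelConfig
from .macm import DEFAULT_SEED_RADIUS_MM, CoactivationResult, SeedROI, run_macm
from .robustness import (DEFAULT_FSN_RATES, FSNResult, JackknifeResult,
                         fail_safe_n, jackknife)
from .spaces import dataset_to_mni

__all__ = ["ContrastConfig", "RunManifest", "ContrastRunResult", "run_contrast",
           "run_macm_stage", "load_config"]

log = logging.getLogger("alemeta")


@dataclass(frozen=True)
class ContrastConfig:
    """Everything needed to run one contrast end to end."""

    name: str
    foci_path: str
    mask_path: str
    out_dir: str = "."
    voxel_size: float | None = None
    min_experiments: int = 4
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    run_jackknife: bool = True
    run_fsn: bool = True
    fsn_rates: tuple[float, ...] = DEFAULT_FSN_RATES
    fsn_realizations: int = 10
    macm_db_path: str | None = None
    macm_seed_radius: float = DEFAULT_SEED_RADIUS_MM
    macm_seeds: tuple[tuple[float, float, float, float], ...] | None = None
    labels_path: str | None = None      # optional TSV: x, y, z, label
    label_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.min_experiments < 2:
            raise ValueError("min_experiments must be >= 2")


@dataclass
class RunManifest:
    """Reproducibility record: enough to re-run the contrast bit-identically."""

    config: dict
    constants_sha256: str
    seed: int
    software_version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


@dataclass
class ContrastRunResult:
    """Outcome of :func:`run_contrast` — either a refusal or the full outputs."""

    status: str                     # "ok" or "skipped"
    reason: str = ""
    analysis: AnalysisResult | None = None
    jackknife: JackknifeResult | None = None
    fsn: FSNResult | None = None
    macm: list[CoactivationResult] = field(default_factory=list)
    manifest: RunManifest | None = None
    table_path: str | None = None


def _config_snapshot(cfg: ContrastConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["inference"] = dataclasses.asdict(cfg.inference)
    d["kernel"] = dataclasses.asdict(cfg.kernel)
    return d


def lookup_labels(peaks_mm: np.ndarray, labels_path: str,
                  radius_mm: float = 10.0) -> list[str]:
    """Nearest-entry anatomical labels from a user-supplied lookup table.

    The table is a TSV with columns x, y, z, label (MNI mm).  A peak
    farther than *radius_mm* from every entry gets "n/a".  No atlas is
    bundled; this hook exists so users can plug in their own.
    """
    table = pd.read_csv(labels_path, sep="\t")
    pts = table[["x", "y", "z"]].to_numpy(dtype=float)
    names = table["label"].astype(str).tolist()
    out = []
    for p in np.atleast_2d(peaks_mm):
        d = np.linalg.norm(pts - p, axis=1)
        i = int(np.argmin(d))
        out.append(names[i] if d[i] <= radius_mm else "n/a")
    return out


def _annotated_table(analysis: AnalysisResult, jk: JackknifeResult | None,
                     fsn: FSNResult | None,
                     labels_path: str | None = None,
                     label_radius_mm: float = 10.0) -> pd.DataFrame:
    """Cluster table with label, jackknife and fail-safe-N columns appended."""
    df = analysis.table.rows.copy()
    if labels_path and not df.empty:
        df["label"] = lookup_labels(df[["x", "y", "z"]].to_numpy(),
                                    labels_path, label_radius_mm)
    if jk is not None:
        df["jackknife"] = [f"{r}/{jk.total_runs}" for r in jk.replicate_count]
    else:
        df["jackknife"] = "-"
    if fsn is not None:
        df["fsn_band"] = [fsn.band[int(c)] for c in df["cluster_no"]]
    else:
        df["fsn_band"] = "-"
    return df


def run_contrast(cfg: ContrastConfig, grid: VoxelGrid | None = None) -> ContrastRunResult:
    """Run every enabled stage of one contrast and write its outputs.

    Emits (under ``cfg.out_dir``): the ALE, voxel-p and cluster-label maps
    as uncompressed NIfTI, the annotated cluster table as TSV, and a JSON
    run manifest.  Returns a refusal report (``status="skipped"``) when the
    contrast has fewer than ``min_experiments`` experiments.
    """
    t_all = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_snapshot(cfg),
                           constants_sha256=constants_checksum(),
                           seed=cfg.inference.seed,
                           software_version=__version__)

    with open(cfg.foci_path) as fh:
        ds = read_sleuth(fh, contrast_name=cfg.name)
    ds = dataset_to_mni(ds)
    log.info("contrast %s loaded %s", cfg.name, ds.summary())

    if ds.n_experiments < cfg.min_experiments:
        reason = (f"Not enough experiments to analyze {cfg.name} "
                  f"{ds.summary()}: {ds.n_experiments} < min_experiments="
                  f"{cfg.min_experiments}")
        log.warning(reason)
        report = out / f"{cfg.name}_refused.txt"
        report.write_text(reason + "\n")
        manifest.outputs.append(str(report))
        manifest.write(out / f"{cfg.name}_manifest.json")
        return ContrastRunResult(status="skipped", reason=reason, manifest=manifest)

    if grid is None:
        grid = make_grid(cfg.mask_path, voxel_size=cfg.voxel_size)

    t0 = time.perf_counter()
    analysis = run_ale_analysis(ds, grid, cfg.kernel, cfg.inference)
    manifest.stage_seconds["ale_inference"] = time.perf_counter() - t0
    log.info("contrast %s: %d cluster(s), corrected=%s", cfg.name,
             len(analysis.table), analysis.table.corrected)

    jk = fsn = None
    can_probe = analysis.table.corrected and not analysis.table.empty
    if cfg.run_jackknife and can_probe:
        t0 = time.perf_counter()
        jk = jackknife(ds, grid, cfg.kernel, cfg.inference, baseline=analysis)
        manifest.stage_seconds["jackknife"] = time.perf_counter() - t0
    if cfg.run_fsn and can_probe:
        t0 = time.perf_counter()
        fsn = fail_safe_n(ds, grid, cfg.kernel, cfg.inference, rates=cfg.fsn_rates,
                          n_realizations=cfg.fsn_realizations, baseline=analysis)
        manifest.stage_seconds["fail_safe_n"] = time.perf_counter() - t0

    # file outputs
    paths = {
        "ale": out / f"{cfg.name}_ale.nii",
        "p": out / f"{cfg.name}_p.nii",
        "clusters": out / f"{cfg.name}_clusters.nii",
        "table": out / f"{cfg.name}_clusters.tsv",
    }
    grid.to_image(analysis.ale.data).to_filename(str(paths["ale"]))
    grid.to_image(analysis.p_values).to_filename(str(paths["p"]))
    grid.to_image(analysis.cluster_labels.astype(np.int16)).to_filename(str(paths["clusters"]))
    table = _annotated_table(analysis, jk, fsn, cfg.labels_path,
                             cfg.label_radius_mm)
    table.to_csv(paths["table"], sep="\t", index=False, float_format="%.8f")
    manifest.outputs.extend(str(p) for p in paths.values())

    result = ContrastRunResult(status="ok", analysis=analysis, jackknife=jk,
                               fsn=fsn, manifest=manifest,
                               table_path=str(paths["table"]))

    if cfg.macm_db_path:
        t0 = time.perf_counter()
        result.macm = run_macm_stage(cfg, grid, analysis)
        manifest.stage_seconds["macm"] = time.perf_counter() - t0

    manifest.stage_seconds["total"] = time.perf_counter() - t_all
    manifest.write(out / f"{cfg.name}_manifest.json")
    return result


def run_macm_stage(cfg: ContrastConfig, grid: VoxelGrid,
                   analysis: AnalysisResult | None) -> list[CoactivationResult]:
    """One co-activation analysis per seed.

    Seeds come from the explicit ``macm_seeds`` list when given, otherwise
    from the corrected cluster peaks of the main analysis (skipped with a
    warning when there are none).
    """
    if not cfg.macm_db_path:
        return []
    if cfg.macm_seeds is not None:
        seeds = [SeedROI(centre=(x, y, z), radius=r) for x, y, z, r in cfg.macm_seeds]
    elif analysis is not None and analysis.table.corrected and not analysis.table.empty:
        seeds = [SeedROI(centre=(row.x, row.y, row.z), radius=cfg.macm_seed_radius)
                 for row in analysis.table.rows.itertuples()]
    else:
        log.warning("MACM stage skipped: no corrected cluster peaks and no "
                    "explicit seed list")
        return []

    with open(cfg.macm_db_path) as fh:
        db = dataset_to_mni(read_sleuth(fh, contrast_name="macm_db"))
    out = Path(cfg.out_dir)
    results = []
    for i, roi in enumerate(seeds, start=1):
        res = run_macm(db, roi, grid, cfg.kernel, cfg.inference)
        log.info("MACM seed %d %s selected %s", i, roi.describe(), res.selection.summary())
        res.summary_frame().to_csv(out / f"{cfg.name}_macm_seed{i}_selection.tsv",
                                   sep="\t", index=False)
        res.analysis.table.to_tsv(out / f"{cfg.name}_macm_seed{i}_clusters.tsv")
        results.append(res)
    return results


def load_config(path: str, name: str | None = None) -> list[ContrastConfig]:
    """Parse a YAML pipeline config into per-contrast configs.

    Layout: top-level defaults (mask, thresholds, toggles) plus a
    ``contrasts:`` list of per-contrast sections that override them.
    """
    raw = yaml.safe_load(Path(path).read_text())
    defaults = {k: v for k, v in raw.items() if k != "contrasts"}
    configs = []
    for entry in raw.get("contrasts", []):
        merged = {**defaults, **entry}
        inf_kwargs = merged.pop("inference", {})
        ker_kwargs = merged.pop("kernel", {})
        merged["inference"] = InferenceConfig(**inf_kwargs)
        merged["kernel"] = KernelConfig(**ker_kwargs)
        if "fsn_rates" in merged:
            merged["fsn_rates"] = tuple(merged["fsn_rates"])
        if merged.get("macm_seeds") is not None:
            merged["macm_seeds"] = tuple(tuple(s) for s in merged["macm_seeds"])
        configs.append(ContrastConfig(**merged))
    if name is not None:
        configs = [c for c in configs if c.name == name]
        if not configs:
            raise KeyError(f"no contrast named {name!r} in {path}")
    if not configs:
        raise ValueError(f"config {path} defines no contrasts")
    return configs
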