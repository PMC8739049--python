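"""Permutation null, voxel p-values, cluster labeling and FWE correction."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from alemeta.ale import ALEMap
from alemeta.inference import (InferenceConfig, NullDistribution,
                               PermutationEngine, build_null, label_clusters,
                               run_ale_analysis, threshold_and_correct, voxel_p)
from tests.conftest import random_dataset


@pytest.fixture(scope="module")
def null_ds(brain_grid_4mm):
    rng = np.random.default_rng(100)
    return random_dataset(brain_grid_4mm, rng, n_experiments=6, n_foci=4)


def test_config_validation():
    with pytest.raises(ValueError, match="unstable"):
        InferenceConfig(n_perm=50)
    with pytest.raises(ValueError):
        InferenceConfig(p_voxel=0.0)
    with pytest.raises(ValueError):
        InferenceConfig(connectivity=10)


def test_null_is_deterministic_given_seed(brain_grid_4mm, null_ds):
    cfg = InferenceConfig(n_perm=100, seed=42)
    a = build_null(null_ds, brain_grid_4mm, None, cfg)
    b = build_null(null_ds, brain_grid_4mm, None, cfg)
    assert np.array_equal(a.voxel_ale_samples, b.voxel_ale_samples)
    assert np.array_equal(a.max_cluster_sizes, b.max_cluster_sizes)
    c = build_null(null_ds, brain_grid_4mm, None, InferenceConfig(n_perm=100, seed=43))
    assert not np.array_equal(a.max_cluster_sizes, c.max_cluster_sizes)


def test_permutations_preserve_experiment_bookkeeping(brain_grid_4mm, null_ds):
    engine = PermutationEngine(null_ds, brain_grid_4mm)
    assert [(nf, n) for _, nf, n in engine.experiments] == \
        [(e.n_foci, e.n) for e in null_ds.experiments]
    rng = np.random.default_rng(0)
    draw = engine.draw_foci(rng)
    assert len(draw) == null_ds.n_foci
    assert draw.min() >= 0 and draw.max() < brain_grid_4mm.n_voxels


def test_cached_and_recomputed_null_paths_agree(brain_grid_4mm, null_ds):
    cfg = InferenceConfig(n_perm=100, seed=9)
    cached = build_null(null_ds, brain_grid_4mm, None, cfg)
    tiny = InferenceConfig(n_perm=100, seed=9, max_store_bytes=0)
    recomputed = build_null(null_ds, brain_grid_4mm, None, tiny)
    # the pooled sample is identical; max sizes agree up to float32 rounding
    assert np.array_equal(cached.voxel_ale_samples, recomputed.voxel_ale_samples)
    assert np.abs(cached.max_cluster_sizes - recomputed.max_cluster_sizes).max() <= 1


def _fabricated_null(n_perm=100, samples=None, max_sizes=0):
    samples = np.zeros(1000) if samples is None else np.sort(samples)
    return NullDistribution(voxel_ale_samples=samples,
                            max_cluster_sizes=np.full(n_perm, max_sizes),
                            ale_cutoff=float(samples[-1]), n_perm=n_perm,
                            p_voxel=0.001)


def test_voxel_p_add_one_rule(box_grid_2mm):
    grid = box_grid_2mm
    rng = np.random.default_rng(1)
    samples = rng.random(999)
    null = _fabricated_null(samples=samples)
    data = np.zeros(grid.shape)
    data[0, 0, 0] = 2.0  # above every null sample
    ale = ALEMap(data=data, grid=grid, n_experiments=1)
    p = voxel_p(ale, null)
    assert p[1, 1, 1] == 1.0                       # ALE = 0: every sample >= it
    assert p[0, 0, 0] == pytest.approx(1.0 / 1000)  # above all: 1/(1+N)


def test_voxel_p_matches_naive_rank(box_grid_2mm):
    grid = box_grid_2mm
    rng = np.random.default_rng(2)
    samples = rng.random(500)
    null = _fabricated_null(samples=samples)
    data = rng.random(grid.shape) * 1.2
    ale = ALEMap(data=data, grid=grid, n_experiments=1)
    p = voxel_p(ale, null)
    for _ in range(50):
        ijk = tuple(rng.integers(0, 20, 3))
        naive = (1 + np.sum(samples >= data[ijk])) / (1 + len(samples))
        assert p[ijk] == pytest.approx(naive, abs=1e-12)


def test_cluster_labeling_definitions(box_grid_2mm):
    grid = box_grid_2mm
    single = np.zeros(grid.shape, dtype=bool)
    single[5, 5, 5] = True
    df, _ = label_clusters(single, grid, 26)
    assert len(df) == 1 and df.loc[0, "volume_mm3"] == pytest.approx(8.0)

    face = np.zeros(grid.shape, dtype=bool)
    face[5, 5, 5] = face[5, 5, 6] = True
    for conn in (6, 18, 26):
        df, _ = label_clusters(face, grid, conn)
        assert len(df) == 1

    corner = np.zeros(grid.shape, dtype=bool)
    corner[5, 5, 5] = corner[6, 6, 6] = True
    assert len(label_clusters(corner, grid, 6)[0]) == 2
    assert len(label_clusters(corner, grid, 26)[0]) == 1


def _flood_fill_sizes(binary, conn):
    """Independent BFS flood-fill oracle for connected-component sizes."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (conn == 6 and order == 1) or (conn == 18 and order <= 2) \
                        or conn == 26:
                    offs.append((dx, dy, dz))
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    shape = binary.shape
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        q, size = deque([start]), 0
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            size += 1
            for dx, dy, dz in offs:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < shape[i] for i in range(3)) \
                        and binary[n] and not seen[n]:
                    seen[n] = True
                    q.append(n)
        sizes.append(size)
    return sorted(sizes)


@pytest.mark.parametrize("conn", [6, 26])
def test_labeling_matches_flood_fill_oracle(conn):
    from alemeta.grid import VoxelGrid
    rng = np.random.default_rng(conn)
    affine = np.eye(4) * 2.0
    affine[3, 3] = 1.0
    grid = VoxelGrid(mask=np.ones((12, 12, 12), dtype=bool), affine=affine)
    for _ in range(100):
        binary = rng.random((12, 12, 12)) < 0.18
        df, _ = label_clusters(binary, grid, conn)
        assert sorted(df["size_vox"].tolist()) == _flood_fill_sizes(binary, conn)


def _cluster_scenario(grid, n_voxels_in_cluster):
    """An ALE/p pair with one cluster of a chosen voxel count."""
    data = np.zeros(grid.shape)
    flat = np.argwhere(grid.mask)[:n_voxels_in_cluster]
    # carve a compact block: first k voxels of a 4x4x4 corner region
    block = [(i, j, k) for i in range(5) for j in range(5) for k in range(5)]
    for idx, (i, j, k) in enumerate(block[:n_voxels_in_cluster]):
        data[i, j, k] = 0.5 + 0.001 * idx
    ale = ALEMap(data=data, grid=grid, n_experiments=1)
    null = _fabricated_null(samples=np.linspace(0, 0.1, 1000))
    p = voxel_p(ale, null)
    return ale, p, null


def test_extent_filter_boundary_at_300mm3(box_grid_2mm):
    """37 voxels at 2 mm = 296 mm^3 is dropped; 38 voxels = 304 mm^3 survives."""
    grid = box_grid_2mm
    for nvox, expected in ((37, 0), (38, 1)):
        ale, p, null = _cluster_scenario(grid, nvox)
        cfg = InferenceConfig(n_perm=100, extent_mm3=300.0)
        table, _ = threshold_and_correct(ale, p, null, cfg)
        assert len(table) == expected
        if expected:
            assert table.corrected
            assert table.rows.loc[0, "volume_mm3"] == pytest.approx(304.0)
            # FWE p under the fabricated all-zero null max sizes: add-one floor
            assert table.rows.loc[0, "p_cluster_fwe"] == pytest.approx(1 / 101)


def test_uncorrected_fallback_when_fwe_kills_everything(box_grid_2mm):
    """Clusters failing FWE are reported uncorrected (flagged) if extent passes."""
    grid = box_grid_2mm
    ale, p, _ = _cluster_scenario(grid, 40)
    null = _fabricated_null(samples=np.linspace(0, 0.1, 1000), max_sizes=500)
    table, _ = threshold_and_correct(ale, p, null, InferenceConfig(n_perm=100))
    assert len(table) == 1
    assert not table.corrected
    assert not bool(table.rows.loc[0, "corrected_flag"])


def test_thresholds_are_monotone(brain_grid_4mm, null_ds):
    """Stricter p_voxel or larger extent never yields more clusters."""
    grid = brain_grid_4mm
    res = run_ale_analysis(null_ds, grid, cfg=InferenceConfig(n_perm=100, seed=3),
                           warn_outside=False)
    p_map = voxel_p(res.ale, res.null)
    voxel_counts = [int(((p_map < pv) & grid.mask).sum())
                    for pv in (0.01, 0.001, 0.0001)]
    assert voxel_counts == sorted(voxel_counts, reverse=True)

    base = _fabricated_null(samples=np.linspace(0, 0.2, 2000))
    p = voxel_p(res.ale, base)
    n_surviving = []
    for extent in (0.0, 300.0, 1000.0):
        cfg = InferenceConfig(n_perm=100, extent_mm3=extent)
        table, _ = threshold_and_correct(res.ale, p, base, cfg)
        n_surviving.append(len(table))
    assert n_surviving == sorted(n_surviving, reverse=True)


def test_voxel_null_p_values_are_uniform(brain_grid_4mm):
    """Calibration: the null CDF evaluated at a null dataset's ALE is U(0,1).

    The ALE null has an atom at zero (voxels no kernel reaches), so the
    deterministic add-one p has a matching atom at 1 and is sub-uniform.
    The exactly-uniform quantity under exchangeability is the randomized
    (tie-broken) p, which is what the KS test gets.
    """
    from scipy import stats
    grid = brain_grid_4mm
    rng = np.random.default_rng(77)
    pvals = []
    for i in range(50):
        ds = random_dataset(grid, rng, n_experiments=8, n_foci=4, name=f"n{i}")
        res = run_ale_analysis(ds, grid,
                               cfg=InferenceConfig(n_perm=100, seed=5000 + i),
                               warn_outside=False)
        ijk = tuple(grid.mask_indices[rng.integers(0, grid.n_voxels)])
        x = res.ale.data[ijk]
        samples = res.null.voxel_ale_samples
        n = len(samples)
        greater = n - np.searchsorted(samples, x, side="right")
        ties = np.searchsorted(samples, x, side="right") - \
            np.searchsorted(samples, x, side="left")
        pvals.append((greater + rng.random() * (ties + 1)) / (n + 1))
        # the deterministic p dominates the randomized one (conservative)
        assert res.p_values[ijk] >= pvals[-1] - 1e-12
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
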