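"""MA maps and the ALE union: symmetry, oracles, invariants."""

import numpy as np
import pytest

from alemeta.ale import compute_ale, ma_map, MAMap
from alemeta.datasets import Dataset, Experiment, Focus, TAL
from alemeta.inference import PermutationEngine
from alemeta.kernels import KernelConfig, fwhm_for_sample_size, fwhm_to_sigma
from tests.conftest import make_experiment


def _oracle_ma_value(xyz_mm, foci_mm, fwhm, voxel_volume, trunc=3.0, rule="max"):
    """Independent per-voxel evaluation: direct Gaussian density per focus."""
    sigma = fwhm_to_sigma(fwhm)
    vals = []
    for f in np.atleast_2d(foci_mm):
        d2 = float(np.sum((np.asarray(xyz_mm) - f) ** 2))
        if d2 > (trunc * fwhm) ** 2:
            vals.append(0.0)
        else:
            vals.append(voxel_volume * (2 * np.pi * sigma ** 2) ** -1.5
                        * np.exp(-d2 / (2 * sigma ** 2)))
    if rule == "max":
        return max(vals)
    out = 1.0
    for v in vals:
        out *= 1.0 - v
    return 1.0 - out


def test_single_focus_peaks_at_its_voxel(box_grid_2mm):
    grid = box_grid_2mm
    centre = grid.vox_to_mm(np.array([10, 10, 10]))
    m = ma_map(make_experiment("a", 20, centre[None, :]), grid)
    assert np.unravel_index(np.argmax(m.data), grid.shape) == (10, 10, 10)


def test_duplicate_foci_are_idempotent_under_max(box_grid_2mm):
    c = np.array([[1.0, -3.0, 5.0]])
    one = ma_map(make_experiment("a", 20, c), box_grid_2mm)
    two = ma_map(make_experiment("a", 20, np.vstack([c, c])), box_grid_2mm)
    assert np.array_equal(one.data, two.data)


@pytest.mark.parametrize("rule", ["max", "union"])
def test_ma_matches_per_voxel_oracle(box_grid_2mm, rule):
    """50 random voxels against an independent direct Gaussian evaluation."""
    grid = box_grid_2mm
    rng = np.random.default_rng(21)
    foci = rng.uniform(-15, 15, size=(4, 3))
    k = KernelConfig(combine_rule=rule)
    e = make_experiment("a", 17, foci)
    m = ma_map(e, grid, k)
    fwhm = fwhm_for_sample_size(17, k)
    for _ in range(50):
        ijk = tuple(rng.integers(0, 20, 3))
        expected = _oracle_ma_value(grid.vox_to_mm(np.array(ijk)), foci, fwhm,
                                    grid.voxel_volume, rule=rule)
        assert m.data[ijk] == pytest.approx(expected, abs=1e-9)


def test_requires_mni_space(box_grid_2mm):
    e = Experiment("a", 5, (Focus(0, 0, 0, space=TAL),), space=TAL)
    with pytest.raises(ValueError, match="MNI"):
        ma_map(e, box_grid_2mm)


def test_ale_identity_and_closed_form(box_grid_2mm):
    grid = box_grid_2mm
    m = ma_map(make_experiment("a", 20, np.zeros((1, 3))), grid)
    alone = compute_ale([m])
    assert np.array_equal(alone.data, m.data)

    half = MAMap("h1", np.full(grid.shape, 0.5), grid)
    half2 = MAMap("h2", np.full(grid.shape, 0.5), grid)
    both = compute_ale([half, half2])
    assert np.all(both.data[grid.mask] == 0.75)


def test_ale_matches_naive_product_loop(box_grid_2mm):
    grid = box_grid_2mm
    rng = np.random.default_rng(9)
    maps = [MAMap(f"m{i}", rng.random(grid.shape) * 0.2, grid) for i in range(10)]
    ale = compute_ale(maps)
    naive = np.ones(grid.shape)
    for m in maps:
        naive *= 1.0 - m.data
    naive = 1.0 - naive
    assert np.allclose(ale.data[grid.mask], naive[grid.mask], atol=1e-12)


def test_ale_is_bitwise_order_invariant(box_grid_2mm):
    grid = box_grid_2mm
    rng = np.random.default_rng(2)
    maps = [MAMap(f"m{i}", rng.random(grid.shape) * 0.3, grid) for i in range(6)]
    a = compute_ale(maps)
    b = compute_ale(list(reversed(maps)))
    assert np.array_equal(a.data, b.data)


def test_ale_monotone_in_experiments(box_grid_2mm):
    grid = box_grid_2mm
    rng = np.random.default_rng(4)
    maps = [MAMap(f"m{i}", rng.random(grid.shape) * 0.3, grid) for i in range(5)]
    base = compute_ale(maps[:4])
    more = compute_ale(maps)
    assert np.all(more.data >= base.data - 1e-15)
    # and ALE dominates every single MA map
    for m in maps:
        assert np.all(more.data[grid.mask] >= m.data[grid.mask] - 1e-15)


def test_ale_input_validation(box_grid_2mm):
    with pytest.raises(ValueError, match="at least one"):
        compute_ale([])


def test_stamp_engine_agrees_with_direct_evaluation(brain_grid_4mm):
    """Null-path ALE (pasted stamps) equals the direct path for voxel-centre foci."""
    grid = brain_grid_4mm
    rng = np.random.default_rng(13)
    idx = rng.integers(0, grid.n_voxels, size=12)
    exps, pos = [], 0
    for i, nf in enumerate((5, 4, 3)):
        exps.append(make_experiment(f"e{i}", 10 + 20 * i,
                                    grid.mask_centres_mm[idx[pos:pos + nf]]))
        pos += nf
    ds = Dataset("d", tuple(exps))
    direct = compute_ale([ma_map(e, grid) for e in ds.experiments])
    engine = PermutationEngine(ds, grid)
    fast = engine.ale_from_indices(idx)
    assert np.allclose(fast, direct.data, atol=1e-9)
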