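"""Synthetic foci generation: determinism, ground truth, distributions."""

import io

import numpy as np
import pytest

from alemeta.datasets import read_sleuth, write_sleuth
from alemeta.macm import SeedROI, select_by_seed
from alemeta.simulate import (MacmSpec, SimulationSpec, add_planted_focus,
                              default_sample_sizes, generate_dataset,
                              generate_macm_db)

CENTRES = ((0.0, -40.0, 20.0), (30.0, 10.0, 0.0))


def _render(ds):
    buf = io.StringIO()
    write_sleuth(ds, buf)
    return buf.getvalue()


def test_same_spec_and_seed_is_bitwise_identical(brain_grid_4mm):
    spec = SimulationSpec(n_experiments=8, planted_centres=CENTRES, seed=5)
    a, gta = generate_dataset(spec, brain_grid_4mm)
    b, gtb = generate_dataset(spec, brain_grid_4mm)
    assert _render(a) == _render(b)
    assert gta == gtb
    c, _ = generate_dataset(SimulationSpec(n_experiments=8, planted_centres=CENTRES,
                                           seed=6), brain_grid_4mm)
    assert _render(c) != _render(a)


def test_degenerate_spec_puts_one_focus_per_centre(brain_grid_4mm):
    spec = SimulationSpec(n_experiments=5, planted_centres=CENTRES,
                          contribution_prob=1.0, jitter_sd_mm=0.0,
                          background_foci_per_experiment=0, seed=1)
    ds, gt = generate_dataset(spec, brain_grid_4mm)
    for e in ds.experiments:
        assert e.n_foci == 2
        assert {f.as_tuple() for f in e.foci} == set(CENTRES)
    assert all(len(c) == 5 for c in gt.contributors)


def test_all_generated_foci_lie_in_the_mask(brain_grid_4mm):
    for seed in range(10):
        spec = SimulationSpec(n_experiments=10, planted_centres=CENTRES,
                              jitter_sd_mm=15.0, seed=seed)
        ds, _ = generate_dataset(spec, brain_grid_4mm)
        for e in ds.experiments:
            xyz = np.array([f.as_tuple() for f in e.foci])
            assert brain_grid_4mm.mm_in_mask(xyz).all()


def test_centre_outside_mask_is_a_hard_error(brain_grid_4mm):
    spec = SimulationSpec(planted_centres=((150.0, 0.0, 0.0),))
    with pytest.raises(ValueError, match="outside the mask"):
        generate_dataset(spec, brain_grid_4mm)


def test_round_trip_through_sleuth_format(brain_grid_4mm):
    spec = SimulationSpec(n_experiments=6, planted_centres=CENTRES, seed=2)
    ds, _ = generate_dataset(spec, brain_grid_4mm)
    assert read_sleuth(io.StringIO(_render(ds)), contrast_name=ds.contrast_name) == ds


def test_default_sample_sizes_match_field_scale():
    rng = np.random.default_rng(0)
    n = default_sample_sizes(rng, 1000)
    assert n.min() >= 5 and n.max() <= 101
    assert 15 <= np.median(n) <= 30  # median group size ~ e^3.1 = 22


def test_macm_coupling_extremes(brain_grid_4mm):
    A, B = (20.0, -30.0, 10.0), (-20.0, 30.0, 0.0)
    full = MacmSpec(n_experiments=150, region_pairs=((A, B, 1.0),), seed=7)
    db, gt = generate_macm_db(full, brain_grid_4mm)
    assert gt.emitted_coupled[0] == gt.emitted_primary[0]  # coupling 1

    none = MacmSpec(n_experiments=150, region_pairs=((A, B, 0.0),), seed=7)
    _, gt0 = generate_macm_db(none, brain_grid_4mm)
    assert gt0.emitted_coupled[0] == ()


def test_seed_selection_recovers_emitting_subset(brain_grid_4mm):
    """With zero jitter, selecting at A finds exactly the A-emitters plus any
    experiment whose background lands in the seed (checked by brute force)."""
    grid = brain_grid_4mm
    A, B = (20.0, -30.0, 10.0), (-20.0, 30.0, 0.0)
    spec = MacmSpec(n_experiments=150, region_pairs=((A, B, 0.5),),
                    jitter_sd_mm=0.0, seed=11)
    db, gt = generate_macm_db(spec, grid)
    roi = SeedROI(centre=A, radius=4.0)
    selected = {e.id for e in select_by_seed(db, roi, grid).experiments}
    emitters = set(gt.emitted_primary[0])
    assert emitters <= selected
    centre = np.array(A)
    for eid in selected - emitters:
        e = next(x for x in db.experiments if x.id == eid)
        assert any(np.linalg.norm(np.array(f.as_tuple()) - centre) <= 4.0
                   for f in e.foci)


def test_add_planted_focus_targets_named_experiments(brain_grid_4mm):
    grid = brain_grid_4mm
    ds, _ = generate_dataset(SimulationSpec(n_experiments=5, seed=3), grid)
    out = add_planted_focus(ds, (0.0, -40.0, 20.0), ["synth_01", "synth_03"],
                            grid, jitter_sd_mm=0.0)
    for orig, new in zip(ds.experiments, out.experiments):
        if new.id in ("synth_01", "synth_03"):
            assert new.n_foci == orig.n_foci + 1
            assert new.foci[-1].as_tuple() == (0.0, -40.0, 20.0)
        else:
            assert new == orig
    with pytest.raises(KeyError):
        add_planted_focus(ds, (0.0, 0.0, 0.0), ["nope"], grid)
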