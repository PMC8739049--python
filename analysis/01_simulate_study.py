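#!/usr/bin/env python
"""Build the synthetic multi-contrast study used by the downstream drivers.

Emulates a patient-versus-control coordinate-based meta-analysis at the
scale of a typical published study: four analysable contrasts (13 and 14
experiments for the patient<control comparisons, 6 and 5 for the
patient-versus-patient ones) plus one deliberately under-powered contrast
with 2 experiments, which the pipeline must refuse.  Each contrast has a few
planted convergence sites plus uniform background foci; ground truth is
written alongside so later drivers can score recovery.

Outputs: scratch/study/ (foci files, mask, pipeline config) and
results/study_ground_truth.tsv.
"""

from pathlib import Path

import pandas as pd
import yaml

from alemeta.datasets import write_sleuth
from alemeta.grid import make_grid, synthetic_brain_mask
from alemeta.simulate import SimulationSpec, generate_dataset

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

VOXEL_MM = 4.0

# name -> (n experiments, planted centres, contribution prob)
CONTRASTS = {
    "structural_patient_lt_control": (13, ((24.0, 2.0, -22.0),), 0.8),
    "functional_patient_lt_control": (14, ((40.0, -40.0, 20.0), (6.0, -66.0, 6.0),
                                           (-36.0, -40.0, 30.0)), 0.7),
    "structural_comparator_lt_patient": (6, ((-24.0, -36.0, -4.0),), 0.9),
    "functional_patient_lt_comparator": (5, ((20.0, -60.0, -2.0),), 0.9),
    "structural_patient_lt_comparator": (2, ((24.0, 2.0, -22.0),), 1.0),  # refused
}


def main() -> None:
    STUDY.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    mask_path = STUDY / "mask.nii"
    synthetic_brain_mask(voxel_size=VOXEL_MM).to_filename(str(mask_path))
    grid = make_grid(str(mask_path))

    truth_rows = []
    contrast_cfgs = []
    for i, (name, (n_exp, centres, prob)) in enumerate(CONTRASTS.items()):
        spec = SimulationSpec(n_experiments=n_exp, planted_centres=centres,
                              contribution_prob=prob, jitter_sd_mm=5.0,
                              background_foci_per_experiment=4, seed=1234 + i,
                              contrast_name=name)
        ds, gt = generate_dataset(spec, grid)
        foci_path = STUDY / f"{name}.txt"
        with open(foci_path, "w") as fh:
            write_sleuth(ds, fh)
        for row in gt.to_frame().itertuples(index=False):
            truth_rows.append({"contrast": name, **row._asdict()})
        contrast_cfgs.append({"name": name, "foci_path": str(foci_path)})
        print(f"{name}: {ds.summary()} -> {foci_path.name}")

    config = {
        "mask_path": str(mask_path),
        "out_dir": str(STUDY / "out"),
        "min_experiments": 4,
        "inference": {"n_perm": 200, "seed": 2024},
        "fsn_realizations": 3,
        "contrasts": contrast_cfgs,
    }
    (STUDY / "pipeline.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    pd.DataFrame(truth_rows).to_csv(RESULTS / "study_ground_truth.tsv",
                                    sep="\t", index=False)
    print(f"config -> {STUDY / 'pipeline.yaml'}")
    print(f"ground truth -> {RESULTS / 'study_ground_truth.tsv'}")


if __name__ == "__main__":
    main()
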