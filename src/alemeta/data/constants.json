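{
  "comment": "Versioned numeric constants used by the ALE pipeline. Kept in one auditable file rather than hard-coded in logic.",
  "icbm2tal": {
    "description": "Lancaster et al. (2007, Hum Brain Mapp 28:1194-1205) 'icbm2tal' pooled affine mapping ICBM/MNI millimetre coordinates to Talairach millimetre coordinates. The Talairach->MNI direction used for foci conversion is the matrix inverse, computed at load time.",
    "variant": "pooled",
    "mni_to_tal": [
      [0.9357, 0.0029, -0.0072, -1.0423],
      [-0.0065, 0.9396, -0.0726, -1.394],
      [0.0103, 0.0752, 0.8967, 3.6475],
      [0.0, 0.0, 0.0, 1.0]
    ]
  },
  "ale_kernel": {
    "description": "Random-effects spatial-uncertainty calibration of Eickhoff et al. (2009, Hum Brain Mapp 30:2907-2926): empirical between-subject and between-template Euclidean displacement converted to the FWHM of an isotropic Gaussian. Per-experiment FWHM = sqrt(fwhm_subject_mm^2 / n + fwhm_template_mm^2) for sample size n.",
    "fwhm_subject_mm": 17.118,
    "fwhm_template_mm": 8.4113,
    "derivation": "fwhm_subject_mm = 11.6 / (2*sqrt(2/pi)) * sqrt(8*ln 2); fwhm_template_mm = 5.7 / (2*sqrt(2/pi)) * sqrt(8*ln 2); 11.6 mm and 5.7 mm are the calibrated between-subject and between-template Euclidean distances."
  }
}
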