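# Methods

## Model

A focus is one reported peak (x, y, z, MNI mm) from one experiment (a study
contrast with group sample size *n*). The spatial uncertainty of a focus is
modelled as an isotropic 3-D Gaussian whose FWHM combines between-subject
variability, which averages out as 1/sqrt(n), with between-template
variability, which does not:

    FWHM(n) = sqrt(fwhm_subject² / n + fwhm_template²)

The two constants (17.118 mm and 8.4113 mm) derive from the standard
random-effects calibration of coordinate uncertainty (empirical Euclidean
displacements of 11.6 mm between subjects and 5.7 mm between templates,
converted to Gaussian FWHMs); they live in `src/alemeta/data/constants.json`
together with the published MNI→Talairach affine whose inverse converts
Talairach-space foci, and both are config-overridable. For sample sizes
5–101 (the range the generator emulates) FWHM(n) spans ≈ 11.7–8.6 mm.

Kernels are evaluated as density × voxel volume on the analysis grid, so a
focus deposits unit probability mass (kernel truncation at 3 × FWHM keeps
the discrete mass within [0.99, 1.01]). An experiment's modelled-activation
(MA) map combines its foci per voxel with the **max** rule by default: the
value is the largest single-focus probability, so a study reporting many
nearby peaks cannot dominate a voxel. The probabilistic-union rule
(`combine_rule="union"`, MA = 1 − Π(1 − p)) is kept as an option; see
"Single-experiment clusters" below for the one analysis that uses it.
The ALE map is the union across experiments, ALE = 1 − Π(1 − MA); maps are
combined in sorted-experiment-id order so the result is bitwise independent
of input order.

## Inference

The null hypothesis is spatial non-convergence. Each permutation redraws
every experiment's foci uniformly over the in-mask voxel centres —
preserving per-experiment foci counts and sample sizes, hence kernels — and
recomputes ALE. Because null foci sit on the voxel-centre lattice, the
permutation engine pastes precomputed discrete kernel blocks, which agrees
with direct evaluation to 1e-9 and makes a 200-permutation null on a 4 mm
brain grid a ~1 s operation.

* **Voxel level.** ALE values are pooled over in-mask voxels and all
  permutations (subsampled beyond a 2×10⁷-sample cap); the voxel p-value is
  add-one smoothed, p(v) = (1 + #{null ≥ ALE(v)}) / (1 + N). The pooled
  null has an atom at zero (voxels no kernel reaches), so p has a matching
  atom at 1 and is conservative there; the calibration test therefore
  checks the randomized-tie-broken p, which is exactly uniform under
  exchangeability.
* **Cluster level.** The map is binarized at p < p_voxel (default 0.001),
  components are labelled at 26-connectivity (configurable: 6/18/26), and
  each cluster's FWE p is the add-one fraction of permutations whose
  *maximum* cluster size reaches its size. Clusters need FWE p < 0.05 and
  volume ≥ 300 mm³. If none qualify, the uncorrected suprathreshold
  clusters (still extent-filtered) are reported with
  `corrected_flag=False`, mirroring the conventional fallback report.
* The per-permutation max-cluster pass needs the pooled cutoff first, so
  `build_null` is two-phase; permutation maps are cached in float32 under a
  512 MB cap, otherwise recomputed from the cached foci draws. Either path
  is deterministic given the seed.

Defaults (p_voxel 0.001, cluster-FWE 0.05, 1000 permutations, 300 mm³
extent) are the field's standard settings for this workflow; tests and the
acceptance script run 100–250 permutations, which leaves the FWE decision
granularity at 1/(n_perm+1) ≤ 0.01 — ample for α = 0.05 — while keeping the
whole suite within minutes.

## Robustness procedures

**Jackknife.** The corrected analysis is rerun E times leaving out one
experiment each; a baseline cluster replicates in a run if the run's
corrected-significant map overlaps it by ≥ 1 voxel (the weakest auditable
spatial-matching criterion; the analysis is insensitive to stricter overlap
for compact clusters). Runs whose own corrected table is empty replicate
nothing.

**Fail-safe N.** For rates {6, 10, 20, 30}% (the bands conventionally
reported), m = ceil(rate × E) synthetic null experiments are appended; each
draws its focus count and sample size with replacement from the dataset's
own empirical distributions and scatters foci uniformly over the mask. A
cluster survives a rate if it overlaps a corrected cluster in ≥ 50 % of the
realizations (default 10; 3–5 in the drivers and tests); the reported band
brackets the highest surviving rate. An iterative search for the exact
fail-safe integer is deliberately not performed — bands are what the
workflow reports.

**Single-experiment clusters.** Under the default max rule a lone
experiment's ALE is capped at its single-kernel peak, which sits at or
below the pooled null's 99.9th percentile; a corrected single-experiment
cluster is therefore essentially unconstructible — by design of the
modified (non-additive) ALE, and reinforced by the permutation null
preserving per-experiment foci counts. The jackknife counterexample (a
cluster that dies exactly when its one source study is excluded) is
accordingly constructed under the union rule, where a single study
reporting many co-localised peaks can reach significance.

## MACM

A seed (6 mm sphere at a corrected peak by default, or an explicit mask)
selects every database experiment with ≥ 1 focus inside it; the corrected
ALE of that subset is the seed's co-activation map. The seed region itself
converges by construction (self-co-activation); additional corrected
clusters indicate coupling. Sphere membership uses exact Euclidean
distance; mask membership uses voxel rounding — both seed kinds are
supported because published workflows are ambiguous between spherical ROIs
at peaks and whole-cluster masks.

## Synthetic data

The generator emulates the study conditions of a typical
patient-versus-control coordinate-based meta-analysis: 5–14 experiments per
contrast, group sizes round(LogNormal(μ=3.1, σ=0.5)) clipped to [5, 101]
(median ≈ 22), ~5 background foci per experiment placed uniformly on the
in-mask voxel-centre lattice (exactly the permutation null's distribution,
so background is null-like by construction), and planted convergence sites:
each experiment contributes, per site, one focus at centre + isotropic
Gaussian jitter (per-axis SD, default 6 mm) with probability
`contribution_prob` (default 0.7). Jittered foci are snapped to the nearest
in-mask voxel centre when they fall outside. The MACM generator plants
region pairs: an experiment emits a focus near A with probability 0.3 and,
conditionally, near B with the pair's coupling probability; the remaining
focus budget is background. The analysis mask is a required input; an
ellipsoidal synthetic brain mask (semi-axes 70 × 85 × 70 mm, ≈ 1.7 l) stands
in for a tissue mask in simulations.

What the simulations do **not** emulate: anatomically structured gray-matter
masks (convergence rates near tissue boundaries differ), non-uniform base
rates of reported activations across the brain, modality differences (VBM
vs PET/SPECT) beyond foci counts, and correlated multi-peak reporting
within studies. Passing tests therefore certify the algorithmic and
frequentist properties of the pipeline, not the anatomical validity of any
particular real-data result.

## Operating characteristics measured

With 14 experiments of ~5 uniform foci on a 4 mm brain grid and 200
permutations, the family-wise false-positive rate at α = 0.05 is
consistent with nominal (binomial [0.02, 0.09] band over 200 datasets).
Planted-cluster recovery under the default generator conditions
(contribution 0.7, jitter 6 mm) is intrinsically partial: Binomial(14, 0.7)
leaves a ≈ 25 % per-dataset chance that some site has ≤ 7 contributors,
and such a site's suprathreshold extent (~500–700 mm³) is of the same order
as the null's 95th-percentile maximum cluster size, i.e. at the detection
boundary of max-cluster-size FWE inference; per-axis 6 mm jitter also puts
the mean 3-D focus displacement at 9.6 mm, so recovered peaks can
legitimately exceed a 10 mm localisation radius. The measured
all-three-sites recovery rate is ≈ 0.6 per seed at 2 mm resolution — a
property of the study conditions and the (deliberately conservative)
cluster-level statistic, not an implementation artefact; individual strong
sites (≥ 9 contributors) are recovered nearly always with peaks a few mm
from the planted centres.

## Numerical and degenerate-input conventions

Ties at the voxel threshold resolve conservatively (binarization is
strictly "greater than cutoff", matching the add-one p definition); cluster
tables sort by volume then max ALE, descending, with stable order; peak =
first voxel attaining the cluster maximum in scan order. Foci outside the
mask are retained (kernel mass contributes only inside) and reported in a
warning listing the offending experiment ids. Datasets with a single
experiment are analysable (ALE = MA) but jackknife requires ≥ 2 experiments
and the pipeline guard refuses contrasts below `min_experiments`
(default 4: published analyses run at 5–14 experiments and refuse at 2–3).
Noise rates must lie in (0, 1]; permutation counts below 100 are rejected
as giving an unstable null tail.
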