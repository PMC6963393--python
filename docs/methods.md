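# Methods

## The measurement problem

Carotid intraplaque hemorrhage (IPH) is hyperintense on MPRAGE because
methemoglobin shortens T1. Two quantification routes coexist: a reader
delineating the lesion (assisted by region-based level-set software), and a
semi-automatic rule thresholding at a percentage of the mean signal of the
sternocleidomastoid muscle (SCM). The package implements both and the
statistics that compare them, on synthetic subjects whose ground truth is
known exactly.

## Phantom model

Each subject is a 64 × 64 × 16 voxel grid at 0.31 × 0.31 × 1.0 mm (the
reconstructed in-plane resolution and slice thickness of the emulated
protocol; axis 2 is the slice axis). The scene is built from analytic
primitives evaluated at voxel centres, so the true IPH volume is exactly
(voxel count) × 0.0961 mm³:

| component | geometry | noiseless intensity (a.u.) |
|---|---|---|
| background | — | 20 (MPRAGE suppresses background) |
| lumen | cylinder, radius 2.5 mm | 10 (black blood) |
| wall | annulus, 1 mm thick | 100 (isointense to muscle) |
| plaque | 140° sector thickened 2.5 mm, slices 2–13 | 100 |
| IPH | ellipsoid inside the plaque | `ratio × 100` |
| muscle (SCM) | rectangular block away from the vessel | N(100, 5²) per voxel |

Noise is Rician by default (σ = 5, i.e. SNR ≈ 20 against muscle — typical
for 3 T neck imaging): the magnitude of a complex Gaussian perturbation,
which is the actual statistics of MR magnitude images. Gaussian noise is
retained because its mean/variance are analytically trivial, which the tests
exploit. The muscle's intra-ROI variability (SD 5) gives the three-point
reference estimate realistic sampling error (SD ≈ 4 a.u. after scan noise),
which is the dominant source of per-subject threshold jitter.

The default cohort is 40 subjects. Contrast ratios are uniform on
(1.3, 3.0): no population distribution of IPH contrast is established, so
this range spans clearly sub-threshold to clearly supra-threshold lesions
and is exposed in `CohortSpec`, not claimed to describe any patient
population. IPH ellipsoid semi-axes are uniform on 0.8–1.2 mm (radial,
bounded by the plaque thickness), 1.5–3.0 mm (tangential) and 2.0–5.0 mm
(axial, guaranteeing ≥ 3 occupied slices), giving true volumes of roughly
10–75 mm³. Per-subject seeds derive from the master seed through one
`numpy` generator, so a cohort is a pure function of its spec.

What the phantom does **not** emulate: pulse-sequence physics, coil
sensitivity fields (a known caveat for SCM-referenced thresholds with
surface coils), k-space artefacts, anatomical shape variation, and —
importantly — intra-lesion intensity heterogeneity: IPH voxels share one
noiseless intensity, so a threshold tends to keep or remove a lesion almost
wholesale rather than eroding it gradually. Passing tests therefore
demonstrate the *mechanism* linking threshold strictness to agreement loss,
not clinical accuracy on real plaque.

## Semi-automatic route

`segment_iph` composes four stages, each independently testable:

1. **Reference**: arithmetic mean of exactly three SCM sample points
   (configurable count); a non-positive mean is an error since ratios are
   then undefined.
2. **Threshold**: strict `I > r · μ_SCM` (the `>` convention follows the
   printed notation of the criteria; ties are excluded, and a non-strict
   variant is available).
3. **Consecutive-slice rule**: 26-connectivity 3-D components whose
   slice-index support contains no run of ≥ 2 consecutive indices are
   removed. The rule's scope is per component by default; whether clinical
   software applies it per component or to the mask as a whole is not
   documented, so `scope="mask"` is provided. 26-connectivity is the most
   permissive standard choice; 6 and 18 are selectable.
4. **Metrics**: total volume = count × voxel volume; maximal axial volume =
   the largest single-slice count × voxel volume; length = (last − first
   occupied slice + 1) × dz, i.e. gaps inside the lesion count toward
   length. Both interpretations are isolated in `compute_metrics`.

Plaque qualification (`qualify_plaque`, wall > 2 mm on two consecutive
slices, strict) operates on reader-supplied thicknesses; estimating wall
thickness from images is out of scope.

## Manual proxy: two-phase region contour

Reported manual workflows use a "piecewise smooth regional level set". With
no parameters published, the reproducible member of that family is the
piecewise-constant two-phase (Chan–Vese) energy, implemented here restricted
to the plaque domain D:

E(M) = λ_in Σ_{v∈M} (I_v − c_in)² + λ_out Σ_{v∈D∖M} (I_v − c_out)² + μ·Per(M)

with c_in/c_out the region means and Per the count of in-plane 4-neighbour
label disagreements. Evolution is slice-wise 2-D (no coupling across
slices, matching how axial images are read); the 3-D consecutive-slice rule
and metrics are applied afterwards through the same code path as the
threshold route.

Numerical scheme: intensities are min–max normalised over D so μ is
scale-free (default μ = 0.05, λ_in = λ_out = 1). The energy is minimised by
synchronous local-cost reassignment sweeps (each voxel takes the phase with
the smaller data-plus-boundary cost, then the means are refreshed) with an
explicit accept/reject guard: a sweep that would raise the energy is
rejected and evolution stops. Energy is therefore non-increasing across
accepted iterations by construction — the property the tests assert. The
`dt` field is kept for interface compatibility with gradient-descent
formulations; the discrete scheme corresponds to its stable large-step limit
and does not consume it. Convergence: identical mask, or relative change of
both region means below `tol` (1e-4); cap `max_iters` = 200. The
segmentation is fully deterministic.

Initialisation: the 150%-of-muscle threshold mask when a reference is
supplied (an automatic, reproducible seed); when no reference exists or that
seed is empty — which happens for lesions below 1.5× muscle — Otsu's
threshold within the plaque provides the seed. A supplied-mask mode
supports warm starts and fixed-point tests. A plaque with zero intensity
range is rejected as degenerate (no contrast to segment).

The piecewise-smooth variant (spatially varying region models) is a
documented extension point, not implemented. This proxy's agreement with
human readers cannot be validated from published information; it stands in
for manual reading only in the sense of being threshold-free and
contrast-driven.

## Agreement statistics

ICC is computed from the two-way subjects × methods ANOVA mean squares,
single-rater forms: ICC(1), ICC(C,1), ICC(3,1)-style consistency, and
ICC(A,1) absolute agreement — the default, because the quantity itself
(volume in mm³) must match across methods, not merely correlate. Estimates
are clipped to [−1, 1] against ~1e−15 rounding overshoot. Zero total
variance is an error, as is n < 3 (estimation) or n < 5 (CI; both floors
configurable).

CIs default to Fisher-z: tanh(atanh(ρ̂) ± 1.96/√(n−3)). Exact F-based
intervals (Shrout–Fleiss for one-way/consistency, McGraw–Wong with
Satterthwaite degrees of freedom for absolute agreement) are available via
`ci_method="f"` and are cross-checked against an independent implementation
in the tests. Monte-Carlo calibration at true ICC 0.8, n = 40 puts the
Fisher-z coverage at ≈ 95–96%: slightly conservative, because 1/√(n−3)
marginally overstates the sampling SD of z(ICC) for paired data.

Two ICCs are compared by the normal test on the difference of Fisher-z
transforms with SE √(1/(n_a−3) + 1/(n_b−3)), one-sided by default
(H_A: ρ_a > ρ_b). This assumes independent cohorts; in the simulated study
the three ICCs share the manual arm, so the test is approximate there — a
subject-resampling bootstrap (`compare_icc_bootstrap`) is provided for the
dependent case, labelled as an extension. Bonferroni multiplies each raw p
by the number of comparisons actually run (m = 2 by default), clipped at 1;
significance is declared at α = 0.05 on adjusted values.

The six-band interpretation scale assigns `v ≤ 0 → poor`, then upper edges
0.20 (slight), 0.40 (fair), 0.60 (moderate), 0.80 (substantial), 1.00
(almost perfect); printed boundaries belong to the band whose interval
contains them (0.20 → slight, 0.81 → almost perfect), and negative values
report as poor.

## Study pipeline

`run_study` is deterministic given the master seed (recorded with a config
hash in the provenance block): simulate → segment each subject with the
manual proxy and the 1.5/1.75/2.0 criteria → ICC of total volume per
criterion against the manual arm → one-sided comparisons 150% > 200% and
175% > 200% with Bonferroni m = 2. A `manual_mode="truth"` switch replaces
the level-set arm with the ground-truth volumes for statistical experiments
uncontaminated by segmentation error. Exports: per-subject metric table,
ICC table with bands, comparison table, and a long-format per-subject volume
table for plotting.

## Problem sizes and numerical choices

Tests and the acceptance script use the defaults above: 64×64×16 grids,
40-subject cohorts, 25 master seeds for the threshold-ordering property,
2 000 replicates for CI coverage and test calibration, 50 random ≤ 32³
grids for brute-force equivalence. A full seeded study runs in under a
second; the entire suite in well under a minute. Ties at thresholds are
excluded (strict `>`); component labelling uses `scipy.ndimage`; the
level-set tie (equal phase costs) assigns the voxel outside; empty masks are
valid segmentations with all-zero metrics.

## Known limitations

* Uniform noiseless IPH intensity makes threshold failure near-binary per
  subject; real lesions erode gradually, so simulated ICC gaps between
  criteria are sharper than clinical ones.
* The Fisher-z comparison ignores the shared manual arm (use the bootstrap
  for the dependent design).
* The level-set proxy is not validated against human readers.
* No DICOM ingestion, registration, resampling, or coil-sensitivity
  correction; NIfTI is the only volume interchange format.
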