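# Methods

This note documents the models, conventions and numerical choices behind
`radcorr`, what the synthetic phantoms do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

**Resampling.** Volumes are resampled to an isotropic grid (default 1 mm) by
separable cubic B-spline interpolation with not-a-knot boundary conditions,
axis by axis; output grid point *j* sits at physical coordinate *j*·target,
sharing the origin with the input grid. Not-a-knot was chosen over
mirrored-boundary prefiltering because it reproduces polynomial data exactly
up to the spline order everywhere including the boundary — a linear ramp
resamples with ~1e-13 relative error, which the tests assert. Masks are
interpolated linearly and thresholded at 0.5 (smoother than nearest-neighbor,
still deterministic). When the input grid already matches the target spacing
the step is the identity.

**Intensity re-segmentation.** ROI voxels outside μ ± 3σ of the in-mask
intensity distribution are removed from the mask (population σ). We implement
the exclusion reading of the 3σ rule — voxels are dropped, not clamped —
consistent with its usual definition as a re-segmentation step. σ = 0 leaves
the mask untouched, returns the degenerate range (μ, μ), and flags the result.
Re-segmentation at a fixed range is idempotent (tested).

**Lloyd-Max quantization.** Intensities in the re-segmented ROI are
discretized to Ng = 64 levels by the nearest-code / centroid fixed point:
codebook initialized at the centers of Ng equal-width bins over the
re-segmentation range; convergence when the maximum codebook movement falls
below 1e-8 of the range width, capped at 500 iterations; empty bins keep their
previous codebook value; a value exactly equidistant between two codes takes
the lower level. Deterministic initialization (no random restarts) was chosen
for bit-reproducibility over global optimality — Lloyd is only locally
optimal anyway, and from the equal-width start its per-iteration MSE descent
(asserted in tests) guarantees it never does worse than plain equal-width
binning. If the ROI holds fewer distinct values than Ng, the distinct values
map to consecutive levels 1..k and the effective level count is recorded.
Quantization is invariant to positive affine intensity transforms applied
before re-segmentation (tested).

## Texture features

All matrices are 3D at distance 1 with the merged 13-unique-direction
aggregation: counts from every direction are accumulated into a single matrix
before features are evaluated; per-direction averaging is not offered. One
convention, stated and tested, in line with the extraction package family this
design follows. Consequences:

* **Run percentage** is RP = n_runs / (n_voxels × 13); every in-mask voxel
  lies in exactly one run per direction, so Σ r·M(g,r) = 13·N_v exactly.
* **Zones** are 26-connected components of equal level; Σ z·M(g,z) = N_v.
* **NGTDM** uses the in-mask 26-neighborhood mean; voxels with no in-mask
  neighbor are excluded from the level counts N(i). The busyness, coarseness,
  complexity, contrast and strength formulas follow Amadasun & King, with a
  stabilizer ε = 1e-6 in the coarseness/strength denominators; a flat ROI
  reports the capped sentinel coarseness 1/ε.

Gray levels enter all formulas as their 1-based integer values. GLCM features
use the symmetric normalized matrix; entropy is base 2; correlation is flagged
undefined (NaN) at zero marginal variance. First-order statistics are
population moments of the raw (unquantized, re-segmented) intensities;
kurtosis is raw, not excess; skewness/kurtosis are undefined at σ = 0.
Undefined values propagate as NaN and are handled pairwise-complete
downstream, never silently zeroed.

**Volume normalization.** Exactly seven features are volume-normalized:
GLRLM GLN and RLN, GLSZM GLN and ZSN (type 1,
feature / V), NGTDM strength (type 2, feature × V), NGTDM busyness (type 3)
and coarseness (type 4), the latter two recomputed from the NGTDM parts with
the per-level *mean* absolute neighborhood difference s(i)/N(i) in place of
the summed s(i). V is the number of ROI voxels, which equals the volume in
mm³ on the 1 mm analysis grid (the normalization as published in the
radiomics literature divides by the pixel count). The type-3 denominator is
Σᵢ Σⱼ |i·pᵢ − j·pⱼ| over occupied levels — printed forms of this formula often
omit the absolute-value bars and the second index, and this is the only
reading that is positive and reduces to the busyness denominator.

## Fiducial artifact masking

The algorithm operates per axial slice in 2D ("layers" and "pixels"); no 3D
connectivity is used. The artifact threshold [μ_AL − 3σ_AL, μ_AL + 3σ_AL] is
estimated over in-ROI voxels on slices not listed in any fiducial's
artifact-slice set; the artifact-slice lists are explicit inputs (in clinical
practice artifact layers are identified visually, so the package does not try
to guess them). On each artifact slice the mask unions
(a) pixels whose center lies within 5 mm of the fiducial (in-plane spacing,
Euclidean pixel-center distance), (b) every in-ROI pixel outside the
threshold — each such pixel is treated as a "distal artifact pixel", with no
restriction to the farthest pixel per ray — and
(c) the Bresenham line from each pixel in (b) to the fiducial center,
restricted to the ROI. Whether out-of-ROI supra-threshold pixels should seed
lines is unstated; they do not here, keeping the mask a subset of the ROI.
Masked voxels are removed (the ROI shrinks); no in-painting. Narrowing the
threshold can only grow the mask (tested as a monotonicity property).

## Synthetic cohort model

The generator emulates the *statistical structure* the analysis assumes, not
scanner physics:

* **Texture.** Per patient, a shared field S and independent per-modality
  fields H_m are white noise smoothed by a Gaussian kernel of width
  ℓ = 3 mm (correlation length, chosen as a plausible soft-tissue texture
  scale at 1 mm voxels), standardized to unit variance. The noiseless image is
  f_m(√w·S + √(1−w)·H_m)·gain_m + offset_m: w is the fraction of texture
  variance shared across modalities, the single dial the parameter-recovery
  tests turn.
* **Transforms.** f_m is monotone: identity (CT-like, CBCT-like — both are
  X-ray attenuation images), negation (T2w-like, emulating the T2-vs-CT
  contrast inversion), or a signed gamma curve (available, not a default).
  Monotone transforms preserve within-ROI ranks up to sign, which is what
  makes Spearman the right correlation for the analysis.
* **Intensity scales.** Defaults: CT gain 25, offset 35, noise σ 4 (soft-tissue
  Hounsfield-like numbers); CBCT the same contrast with noise σ 8 (cone-beam
  images are noisier); T2w gain 120, offset 450, noise σ 12 (arbitrary MR
  signal units). These are one-time realism choices, not tuning knobs.
* **ROI.** An ellipsoid with lognormal radii, median (22, 18, 20) mm and
  σ_log = 0.15 per axis — median volume ≈ 33 cm³ and a 15–70 cm³ cohort
  spread, matching clinical prostate variability. Tests use smaller radii on
  smaller grids; the geometry is otherwise identical.
* **Volume coupling.** Optionally the combined field is scaled by
  exp(c·z), where z is the patient's standardized log ROI volume and
  c = volume_coupling ∈ [0, 1]. At c = 1 intensity-spread features are almost
  perfectly volume-confounded (the volume filter must catch them); at c = 0
  the generator guarantees no coupling beyond sampling noise.
* **Streaks.** Per fiducial and artifact slice, radial in-plane Bresenham
  segments (default 8 per slice, 12 mm long) alternate between +a and −a with
  a = 6 texture standard deviations, plus a bright 3a spike at the seed pixel.
  No quantitative intensity model of clinical metal streaks is available; the
  6σ default is calibrated only to reproduce the qualitative regime in which the
  artifacts are supra-threshold and the run-length/size-zone features are the
  artifact-sensitive ones. Out-of-plane streaks are not modeled. The exact
  altered-voxel set and deltas are recorded, so the artifact-free image is
  reconstructable and mask recall is scorable against ground truth.
* **Determinism.** One global seed spawns a per-patient `SeedSequence`;
  identical specs generate bit-identical cohorts, and each patient is
  independently reproducible.

What a green synthetic test does **not** establish: anything about scanner
physics (beam hardening, bias fields, reconstruction filters), about real
prostate anatomy (zonal structure, rectum/bladder interfaces), or about the
clinical contouring workflow (masks here are exact ellipsoids, not rigidly
transferred human contours). The phantoms validate the *pipeline* — that it
recovers planted correlation structure, flags planted confounding, and removes
planted artifacts — not the clinical findings themselves.

## Correlation study conventions

* The volume filter (|ρ| with same-modality volume > 0.75 → feature removed)
  runs **before** the pair matrix and the BH adjustment, so the BH family is
  unambiguous; volume columns are excluded from the pair matrix and reported
  separately.
* One pooled BH family over the entire upper triangle (the diagonal is
  trivially 1 and excluded), not per comparison class.
* Spearman p-values use the t approximation with df = n − 2 (the n = 47
  regime); an exact-permutation oracle for n ≤ 8 lives in the tests and agrees
  with the approximation to ≤ 0.05 there.
* Missing/undefined feature values are handled pairwise-complete with the
  effective n recorded per pair; pairs with zero rank variance are excluded
  from the BH family and logged.
* Histogram summaries filter on the *adjusted* p < 0.05 — the conservative
  choice where raw-p filtering would also be defensible; both p's are emitted
  per pair.
* The masked-vs-unmasked comparison uses a two-sided paired t test per feature
  (no directional hypothesis is assumed), with the companion Spearman r
  between conditions.

## Power analysis

The "point biserial model" is implemented as the noncentral-t formulation:
df = n − 2, δ = ρ√n/√(1 − ρ²), power = mass of the noncentral t beyond the
two-tailed critical value (the opposite-tail term is added when finite; it
underflows to NaN in scipy far out in the tail and is negligible there). A
Fisher-z normal approximation is provided as a cross-check only; the two agree
to a few percent at moderate n (tested). `required_n` and
`min_detectable_rho` invert the power function by integer bisection and
bisection on (0, 1) respectively.

With these settings the package computes, at alpha = 4.0e-4 and two tails:
power(n = 47, ρ = 0.75) ≈ 1.00, power(n = 47, ρ = 0.3) ≈ 0.06, required
n ≈ 186 for power 0.75 at ρ = 0.3, and minimum detectable ρ ≈ 0.55 at n = 47
and power 0.75 (all recomputed by `examples/power_analysis.py`). Beware that
differently configured correlation power calculators — other noncentrality
conventions, Fisher-z engines, or milder alphas — give materially different
small-effect numbers; this package reports only values its own documented
model computes.

## Numerical choices and degenerate inputs

* Lloyd tolerance 1e-8 × range width, ≤ 500 iterations; boundary ties go to
  the lower level.
* NGTDM ε = 1e-6, surfaced as a parameter; degenerate coarseness = 1/ε.
* Single-voxel ROIs: GLCM undefined (flagged NaN); GLRLM gives 13 unit runs.
* Whole-ROI artifact masks, empty resampled masks, and all-artifact slice sets
  raise errors naming the case rather than producing empty results.
* Texture matrices are computed on the ROI bounding box (a pure optimization;
  all matrices depend only on in-mask voxels).

## Limitations

* 3D merged-direction aggregation is the only extraction convention offered;
  packages that average per-direction matrices will give different GLCM/GLRLM
  feature values.
* Only volume is computed among shape features; no filtered (wavelet/LoG)
  features; bin counts other than 64 are configurable but exercised in tests
  only at small values.
* The DICOM-series reader is out of scope; NIfTI is the interchange format.
* The file-based pipeline runs single-threaded; cohort-scale studies are
  minutes, not seconds.
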