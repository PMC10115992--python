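# Methods

This note records the models behind `aceval`, the parameter defaults and why
they were chosen, and what the synthetic phantoms can and cannot show about
real patient data.

## Coordinate and grid conventions

Volumes are axis-aligned grids with 0-based voxel indices;
`physical = origin + index · spacing`, all distances in mm. Every
multi-volume operation requires identical grids. Resampling
(nearest-neighbour for masks and label maps, trilinear for continuous
images) is an explicit step at pipeline entry, never implicit, so any
interpolation of inputs is visible in the analysis record. The interpolation
used to bring a reference CT onto the anatomical grid is a user choice for
the same reason.

Gaussian smoothing is specified by FWHM (σ = FWHM / 2√(2 ln 2)) with
reflective boundaries: constants are preserved, the discrete kernel
integrates to one, and the shape-deviation statistic is not attenuated at
volume edges. Peak locations and all argmax operations break ties toward
the lowest linear index in (z, y, x) order so results are deterministic.

## Tumor delineation

The biological tumor volume (BTV) is the 26-connected union of brain voxels
with TBR = activity / background strictly above the threshold (default 1.6),
after removal of user-supplied physiological exclusion masks (vascular
structures, pineal body and similar). Both boundaries in the protocol are
worded "above", so they are implemented strictly: TBR exactly at threshold is
out, and a reference BTV of exactly 1.0 ml is excluded from PET evaluation.
The BTV keeps *all* suprathreshold components rather than the largest one;
isocontour tools used clinically behave this way, and physiological foci are
handled by the exclusion masks, not by component selection.

The background ROI is an input: clinically it is a region of
healthy-appearing gray and white matter above the insula, drawn or extracted
per patient and per AC method. For phantoms the generator supplies a
crescent of normal tissue in the hemisphere contralateral to the first
lesion, inside an axial slab at a configurable fraction of head height
(default 0.15–0.45 of the superior semi-axis), eroded away from lesion and
brain boundaries. The background mean is computed separately for each
method's PET image, exactly as each method would be normalized in practice.

## Agreement metrics

- **μ classification.** air < 0.05 ≤ tissue ≤ 0.1 < bone (cm⁻¹). The printed
  class interval "0.05–0.1" is read as closed, so both boundary values are
  tissue. Negative μ inside the evaluation region is an error (it indicates a
  broken map, not a class).
- **Proximity sphere.** Class Dice is additionally evaluated inside the
  union of 50-mm spheres centered at each BTV component's TBR maximum
  ("center-of-max" is read as the peak location, configurable to centroid).
- **SSIM** uses a Gaussian window of σ = 1.5 voxels, K1 = 0.01, K2 = 0.03,
  population covariance, data range = reference maximum over the evaluation
  mask, averaged over the mask voxels. The windows are full 3-D; a slice-wise
  2-D variant would differ slightly and is not provided. These constants are
  the standard ones; the protocol does not pin them down.
- **Hausdorff distance** is the maximum over the two directed maximum
  surface-to-surface distances in mm (surfaces = mask minus its erosion); a
  percentile variant (e.g. 95th) is available by configuration since
  published values do not always state which was used.
- **Shape deviation** smooths the binary symmetric difference of two BTV
  masks with a 4 mm FWHM Gaussian and measures the volume where the result
  reaches 1. Smoothed binary images only approach 1 asymptotically, so
  "equals 1" needs a tolerance ε. The statistic's design intent is a
  separation: a one-voxel displacement of the whole contour (a 1-mm shell
  smooths to at most ≈ 0.23) must score zero while a focal blob of clinical
  size must be caught — and the maximum of the smoothed indicator of a
  6-mm-radius ball is P(χ²₃ ≤ (R/σ)²) ≈ 0.994. The default ε = 0.01
  (threshold 0.99) sits in the gap and realizes both design goals; a much
  smaller ε would silently suppress small focal deviations. ε is
  configurable.
- **PSNR** = 10·log₁₀(R²/MSE) with R the reference maximum over the brain;
  identical images report an infinite sentinel rather than an error.

## Clinical evaluation

Acceptance criteria are paired absolute/relative thresholds with OR-pass
semantics — TBRmean ±0.05 or 5 %, TBRmax ±0.1 or 5 %, BTV ±2 ml or 10 %; a
study exceeds the criteria when any metric fails *both* branches. The mix
reflects that larger absolute differences are acceptable in large or very
active tumors.

Tissue banding: the equivocal band (TBRmax in [2.0, 2.4] or TBRmean in
[1.9, 2.1]) takes precedence; otherwise tumor requires TBRmax > 2.4 and
TBRmean > 2.0, else reactive. Evaluating the band first matches how
equivocal readings are described as being "changed to" reactive or tumor by
metric shifts.

Longitudinal change applies the same criteria to baseline→follow-up changes:
the percent-change difference is compared in percentage points against the
relative threshold, OR the absolute-change difference against the absolute
threshold. Direction concordance uses a ±1 % dead band ("stable") so sign
agreement is robust to noise; the dead band is configurable.

TAC pattern classification is a quantitative proxy for the visual reading
used clinically: a least-squares slope over the curve at t ≥ 10 min,
normalized by the late-phase mean, with ±0.15 %/min separating
increasing/plateau/decreasing. The generator's "increasing" pattern
(+20 % from 10 to 40 min ≈ +0.6 %/min) sits well above the threshold, and
the classifier is antisymmetric under time reversal.

## Statistics

Paired metrics are analysed as d = ln(test) − ln(ref), consistent with
right-skewed ratio-scale quantities, and exponentiated back to percent:

    mean % difference = 100·(e^d̄ − 1)
    95 % CI  = 100·(e^{d̄ ± 1.96·SD_d/√n} − 1)
    95 % LoA = 100·(e^{d̄ ± 1.96·SD_d} − 1)

When subjects contribute repeated scans, SD_d uses the one-way ANOVA
decomposition for repeated measurements: total variance = within-subject
mean square + between-subject component (MSB − MSW)/m₀ (clipped at zero),
with m₀ the effective group size. With one scan per subject this reduces
exactly to the ordinary SD. The CI denominator uses the number of subjects
(not scans) — the conservative reading of "corrected for repeated
measurements" — and is configurable. `invert_loa` recovers the mean from the
LoA endpoints (they are log-symmetric around d̄), which doubles as an
internal-consistency check of the construction. Tests are two-sided at
α = 0.05; p-values are reported unadjusted, and identical pairs return a NaN
sentinel for p rather than failing, so null pipelines run end to end.

## The phantom generator

The generator emulates the *study conditions*, not patient anatomy: an
ellipsoidal head (default semi-axes 70 × 85 × 72 mm) with a 6-mm bony shell,
optional spherical air cavities, spherical lesions and physiological foci
with configurable TBR, on a 96³ grid at 2 mm isotropic spacing (desk-scale
runtime with ≈ 0.008 ml voxels, fine enough for 1-ml volume rules).

- μ defaults: air 0.0, tissue 0.096, bone 0.151 cm⁻¹ — standard 511 keV
  values, inside the classification bounds, configurable within them.
- Activity: background level 15 kBq/ml (a typical amino-acid PET background
  for a 200 MBq injection), lesions at TBR × background, extracerebral soft
  tissue at 0.25 × background so the skull-strip masking step has an
  observable effect, zero in air and additive Gaussian noise with σ = 5 % of
  background. Gaussian noise is the simplest model that makes max-statistics
  (TBRmax, peak location) non-degenerate; it does not reproduce the
  spatially correlated, object-dependent noise of iterative reconstruction.
- Artifacts: false bone patches, metal signal voids, air cavities refilled
  with water-equivalent attenuation, missing skull flaps, whole-map
  registration shifts. Sizes and positions are user-specified — published
  artifact taxonomies are qualitative, so no cohort calibration is claimed.
- Dynamics: 14 frames (5 × 1 min, 5 × 3 min, 4 × 5 min; mid-times 0.5 …
  37.5 min) with a shared wash-in ramp to 10 min and a ±20 % late-phase ramp
  for the lesion pattern.

### The attenuation-bias model

Reconstruction is out of scope; instead a first-order model propagates μ-map
error into activity. For attenuation-corrected PET, using the wrong μ-map
scales each line of response by exp(∫ Δμ dl) where Δμ = μ_test − μ_ref. The
model evaluates, per voxel, the mean over K evenly spaced in-plane (axial)
angles of exp of the full-grid line integral through that voxel, and
multiplies the activity by it:

    bias(x) = (1/K) Σₖ exp( ∫_{Lₖ(x)} Δμ dl )

Line integrals use equal-step sampling (default step = half the minimum
spacing) with trilinear lookup, implemented as per-angle projection tables —
an exact reorganization of per-voxel sampling, since the full-line integral
depends only on the line's perpendicular offset within each slice. In-plane
angles match the dominant ring geometry of brain PET; K = 8 by default
(K = 4 already changes results by well under 0.1 % on smooth maps, and step
refinement converges at the same level). The model reproduces closed forms
(uniform Δμ = 0.01 cm⁻¹ over a 20-cm chord gives e^0.2 at the center),
is exactly 1 when the maps agree, and is ≥ 1 wherever Δμ ≥ 0. It deliberately
omits scatter, randoms, the reconstruction operator and its non-local error
propagation, and out-of-plane lines.

### What passing phantom tests does and does not show

Phantom cohorts validate the *protocol implementation*: thresholds, masks,
connected components, criteria logic, statistics and their interactions, with
known ground truth. They do not validate performance claims about any real
attenuation-correction method: real μ-map errors are not spherical, real
noise is not white, real anatomy is not ellipsoidal, and background ROIs in
patients carry placement variability that the generator's deterministic
crescent does not. Cohort-level numbers from phantoms (Dice means, counts of
criteria-exceeding studies) therefore characterize the injected artifact
scenario, not any clinical method.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run phantom cohorts of 10–20
subjects at 96³ × 2 mm (with some module tests at 64³ × 3 mm and oracle
comparisons at ≤ 16³), 100-cohort simulations for statistical parameter
recovery, and the 96³ closed-form bias check. These sizes were chosen so the
whole validation runs in minutes on a single CPU while keeping every rule
(1-ml inclusion, 10-mm peak criterion, 4-mm smoothing) numerically
meaningful at the grid resolution.

## Known limitations

- The bias model is first-order and in-plane; it underestimates non-local
  reconstruction effects of large μ-map errors.
- Skull-stripping, registration and the clinical background-ROI extraction
  tool are out of scope; their masks are inputs.
- SSIM window dimensionality (3-D) and the Hausdorff variant (maximum) are
  fixed defaults where published practice varies; both are configurable.
- The manual four-category artifact reading is carried as an annotation
  field on study records, never computed.
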