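# Methods

This note records the models and procedures `stvquant` implements, the
parameters that matter, and the choices made where the design was open.

## Problem and measurement model

The quantity of interest is synovial tissue volume (STV) on sagittal
T1-weighted fat-suppressed post-contrast knee MRI. Enhancing synovium is
bright; background tissue is dark; vessels also enhance and are the classic
false positive. The measurement is

STV = (number of retained voxels) × dx·dy·dz  [mm³],

where dz is the centre-to-centre slice spacing — slice thickness plus
inter-slice gap (3.0 + 0.3 = 3.3 mm for the default protocol). Using
centre-to-centre spacing makes voxel summation tile the covered anatomy
contiguously; `compute_stv(..., slice_spacing_mm=3.0)` gives thickness-only
volumes for users who prefer to exclude the gap. Retained voxels are treated
as 100% synovitis — no partial-volume weighting — so the volume is an exact
integer multiple of the voxel volume.

## Groupwise registration and the mean reference frame

The pipeline needs a mean reference frame and a per-subject deformation
field; the registration algorithm behind them is a design choice. We use:

* **Pairwise step** (SimpleITK): a translation stage (regular-step gradient
  descent, mean-squares metric), then a B-spline free-form deformation
  (default control mesh 5×5×2, LBFGSB, mean-squares), both with a two-level
  multiresolution schedule (shrink 4/2, smoothing σ 1/0.5 voxels) on
  intensity-normalized images. Fields follow the resampling convention:
  reference coordinates + displacement = subject coordinates. The coarse
  control-point spacing is the smoothness regularizer; at the deformation
  magnitudes the cohort generator produces, the Jacobian of the fitted
  field stays positive (checkable via
  `DeformationField.jacobian_determinant`).
* **Groupwise step**: initial reference = the intensity-median subject;
  then, for 3 outer iterations (default): register all subjects to the
  current reference, re-centre the fields to zero mean displacement (so the
  reference does not drift), and replace the reference with the mean of the
  warped images. Training masks are warped into the final frame with
  nearest-neighbour interpolation and averaged into the probabilistic mean
  mask; `binarize_mean_mask` keeps voxels with occupancy ≥ τ (default 0.25 —
  permissive on purpose, since the mask is meant to *loosely* delimit where
  synovitis occurs).

Registration accuracy is validated by parameter recovery on a textured
(smoothed-noise) volume rather than on the piecewise-constant phantom:
deformation is only observable where the image has gradients, so recovery in
flat regions is undefined. End-point error is likewise evaluated over the
grid interior (excluding a 4-voxel in-plane / 1-slice border) because a
free-form deformation has no image support beyond the boundary. Recovered
translations are accurate to ≲0.1 voxel and smooth 1 mm RMS warps to <1 voxel
mean end-point error at these settings.

## The appearance model

* **Shape**: PCA over the vectorized dense deformation fields (one sample
  per training subject, re-centred to zero mean displacement). Modes with
  eigenvalues below 1e−10 of the leading one are discarded as numerical
  noise; the retained count is the smallest explaining ≥ `var_frac`
  (default 0.95) of variance.
* **Appearance**: PCA over reference-frame intensities of the training
  images (each warped into the frame by its field), with each sample
  normalized to zero mean / unit variance first so the model is indifferent
  to scanner intensity scale.
* **Search** (`fit_aam`): pose is initialized by a coarse exhaustive
  translation scan (±25% of the field of view in-plane in 2-voxel steps,
  ±2 slices through-plane, scored on a stride-2 subgrid) — guarding against
  the gross mask-displacement failure mode — then refined by Nelder–Mead;
  shape coefficients are optimized by bounded coordinate descent (two
  sweeps, each coefficient clamped to ±3 SD of its training spread, the
  standard plausibility constraint), re-refining pose between sweeps. The
  objective is the fraction of normalized target intensity variance that the
  appearance subspace cannot explain, which is also the residual reported
  for quality control. The search has no random element, so fits are exactly
  reproducible.
* **Propagation**: the binarized mean mask, dilated in-plane by 1 voxel
  (default, configurable to 0) to honour the loose-region contract, is
  carried to the target through the numerically inverted field
  (fixed-point inversion, 20 iterations) with nearest-neighbour
  interpolation.

## Targeted thresholding

Two thresholds at fractions of the image maximum (defaults 0.25 and 0.75)
split the *whole image* into a low and a high intensity set; each set's
sample mean and SD (n−1) define a Gaussian PDF. A roi voxel is synovitis iff
its log-density under the high Gaussian exceeds that under the low one;
exact ties are labelled not-synovitis (conservative). Numerical notes:

* The comparison runs in log space: it is mathematically identical to the
  PDF comparison but immune to float underflow in far tails.
* "Maximum" is the literal image maximum by default; `robust_max=True`
  substitutes the 99.9th percentile because a single hot voxel otherwise
  drags both thresholds upward.
* With σ_high > σ_low the quadratic rule acquires a second decision branch
  far below the low mean (extremely dark voxels classified as synovitis).
  The rule is implemented exactly as stated; `monotone=True` instead cuts at
  the single PDF crossing between the means.
* A degenerate (zero-variance) threshold set raises σ to a 1e−6 floor with
  a warning; an empty set is an error naming the offending threshold.

## Edit scripts

Manual corrections are modelled as ordered scripts of four operations:
integer `translate` (voxels shifted past the grid are dropped, with a
warning), `add`/`remove` of explicit voxel lists on a named slice, and
`rethreshold` (refit the intensity model with new fractions and reclassify
inside the current mask). Scripts serialize to YAML/JSON and are hashed
into each result's provenance, so a measurement is replayable bit-exactly.

## Phantom generator

Phantoms emulate the features the method actually depends on: a bright
curved/L-shaped synovium shell of known voxel count (polyline centreline,
2 mm shell, tapered end slices), dark background, bright through-plane
vessel tubes kept ≥5 mm clear of the shell (strictly disjoint from ground
truth), an optional mid-intensity effusion blob, and a bimodal histogram
(defaults N(100, 20²) background, N(800, 40²) enhancing tissue — a
contrast-to-noise ratio typical of post-gadolinium fat-suppressed knees).
The default grid is 64×64×12 at (0.5, 0.5, 3.3) mm, a desk-scale stand-in
for 384×384 clinical stacks. Cohorts warp the noiseless tissue maps and the
ground-truth mask with one smooth random displacement field per subject
(white noise smoothed with σ = (6, 6, 1) voxels, scaled to a 1 mm RMS
target by default, then shrunk if necessary until the Jacobian determinant
stays above 0.2 everywhere — the warp is guaranteed invertible, and
`warp_sigma` is an upper bound on the realized RMS magnitude) and add fresh
per-voxel Gaussian noise. Tissue maps and mask are
warped with the *same* nearest-neighbour rule so every voxel of a warped
subject still belongs to exactly one tissue class and is drawn from that
class's Gaussian — the generator's defining invariant. All randomness flows
from one integer seed through `numpy.random.SeedSequence` spawning.

What the phantoms do **not** model: MR physics (bias fields, Rician noise,
partial-volume mixing at tissue boundaries), anatomy beyond the shell
(bone, cartilage, effusion unless enabled), inter-scanner protocol
differences, and reader behaviour. Passing the phantom suites therefore
demonstrates that the machinery is correct and self-consistent under the
stated imaging model, not that clinical accuracy matches any particular
study.

## Agreement statistics

* `bland_altman`: differences a−b; SD with n−1; CI of the mean difference
  uses the exact t quantile t(0.975, n−1); limits of agreement use the
  conventional 1.96·SD multiplier. These two conventions are deliberately
  different — together they make published (mean difference, CI, LoA)
  triples mutually consistent at small n, which `loa_from_summary` exploits
  to reconstruct LoA from a printed summary.
* `icc_3_1`: two-way mixed-effects, single-measure, *consistency* ICC from
  the ANOVA mean squares, (BMS − EMS)/(BMS + (k−1)·EMS); invariant to
  adding a constant to one rater's column; 95% CI by the standard
  F-distribution (Shrout–Fleiss) interval.
* `agreement_regression`: ordinary least squares of method b on method a
  (slope, intercept, R²). OLS on the continuous volumes is used for
  agreement regression throughout.

## Problem sizes and defaults used in validation

The shipped validation runs train on 8 phantom subjects (3 groupwise
iterations), apply the model to 10 held-out subjects at the default
25%/75% fractions with no edits, and require volume recovery within 5% of
the planted truth; classifier-oracle equivalence is exact on 20 random
phantoms; registration recovery uses one translated and one warped textured
volume. These sizes exercise every code path at full fidelity while keeping
a complete validation run in the minutes range on a single CPU.

## Known limitations

* The B-spline mesh (5×5×2) cannot represent deformations much finer than
  its control spacing; cohorts with sharper warps need a denser mesh (and
  proportionally more runtime).
* The appearance model is trained per cohort; no transfer across protocols
  is attempted, and shape modes from ≤8 subjects span a small subspace.
* The two-PDF rule assumes a bimodal intensity distribution; images without
  a clear high-intensity mode make the high Gaussian fit unstable (the
  fitted model is reported in the provenance for auditing).
* Rigid rotation of the mask is not an edit operation; repositioning is
  translation-only.
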