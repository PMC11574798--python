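# Methods

`reharm` makes longitudinal T2-weighted (T2w) prostate MRI quantitatively
comparable across visits. Two obstacles stand in the way of reading signal
change off serial T2w scans: the patient's anatomy moves and deforms between
visits, and the scanner/sequence combination imposes an arbitrary intensity
scale on every acquisition. The package addresses the first with deformable
image registration to the baseline scan (propagating the baseline contours as
automatic ROIs), and the second with a reference-tissue intensity
harmonization that pins stable tissues to fixed values on a standard scale.
A synthetic pelvis phantom generator provides ground truth for every stage.

## Registration

A follow-up volume is mapped into baseline space in three stages, concatenated
by composition into a single displacement field on the baseline grid:

1. **Rigid pre-alignment** — a 6-DOF transform (Mattes mutual information,
   random 20% sampling, regular-step gradient descent over a 3-level pyramid)
   absorbs repositioning. Mutual information is the default metric because
   visits may differ in intensity scale before harmonization.
2. **Multi-scale symmetric-forces demons** — run coarse-to-fine with shrink
   factors [4, 2] and image-pyramid smoothing sigmas [8, 4] mm, 50 and 25
   iterations per scale with Gaussian field regularization of 1 voxel.
   Symmetric forces keep the update consistent between the forward and
   backward image roles and favour invertible fields. Demons assumes
   comparable intensity scales, so the moving image is histogram-matched to
   the baseline first (1024 levels, 7 match points). The matcher's
   mean-intensity threshold option is deliberately off: when the image mean
   falls inside a large tissue plateau, thresholding includes the plateau in
   one histogram but not the other, and the quantile map derails.
   A scale whose mean-squared error rises by more than 50% to a non-trivial
   level (RMS above 0.5% of the intensity range) aborts with a divergence
   error carrying the per-scale trace; small fluctuations at the noise floor
   are tolerated.
3. **Mutual-information B-spline refinement near the prostate** — treatment
   changes the signal inside the gland, which can defeat the
   intensity-difference force of demons precisely where accuracy matters
   most. A free-form B-spline deformation (16 mm control-point spacing,
   LBFGSB, dense metric evaluation) is optimized for mutual information
   restricted to the prostate mask dilated by 10 mm, and the resulting
   displacement is feathered linearly to exactly zero over one control-point
   spacing outside that region. The increased smoothness demanded of this
   stage is realized by the coarse control grid; no separate bending-energy
   term is used.

Fields follow the resampling convention `warp(image, field)(x) = image(x +
field(x))` with `x` a physical point (mm) on the baseline grid. Composition is
`compose(outer, inner)(x) = inner(x) + outer(x + inner(x))`, so warping with
the composite equals warping by `outer` then by `inner`; the total transform
applies the refinement to the reference point first, then demons, then the
rigid map, which corresponds to warping the moving image rigidly first and
refining last. The rigid transform is folded into the final field
analytically, so one resampling (linear for images, nearest-neighbour for
label masks — labels are never blended) moves any follow-up artifact into
baseline space. Invertibility is monitored as the fraction of body voxels with
positive Jacobian determinant of (identity + field); accepted registrations
require ≥ 99%.

**Degenerate inputs.** Self-registration returns near-zero transforms (the
demons update is identically zero for equal images; the refinement optimizer
starts at a stationary point under dense sampling). Geometry mismatches and
empty prostate masks are hard errors, as is a refinement region smaller than
one control-point cell.

## Harmonization

Three reference tissues bracket the T2w intensity range and are far from the
treated region: gluteus maximus muscle (GM, dark), femur (intermediate) and
bladder urine (bright). Their mean intensities become anchor points mapped to
pre-assigned values 330, 660 and 990 a.u.; boundary anchors pin 0 to 0 a.u.
and the volume's intensity ceiling to 1500 a.u., fixing the output scale to
[0, 1500].

The five anchor pairs are densified by piecewise-linear interpolation
(1024 samples) and fitted with a penalized cubic B-spline — a P-spline with a
second-order difference penalty on the coefficients (default weight 0.1,
dimensionless after normalization by grid density; ~50 uniform knots plus
knots at the anchor positions, where the target has slope kinks). Monotonicity
and non-negativity are enforced structurally: the coefficients are
reparameterized as cumulative sums of non-negative increments and solved
exactly by non-negative least squares; non-decreasing coefficients are a
sufficient condition for a non-decreasing spline. The defaults keep the
maximum anchor residual within 1% of the output scale (warned otherwise), and
the map is exported as a dense monotone lookup table.

Numerical/robustness choices:

- **Intensity ceiling**: the 99.9th-percentile intensity rather than the
  literal maximum, so a handful of hot pixels cannot stretch the scale
  (literal maximum available by flag — with extreme outliers it collapses
  the tissue anchors below the separation threshold and the fit is refused,
  which is the intended failure mode).
- **Fit refusal** ("fit impeded"): anchors inverted relative to the reference
  ordering, or closer together than 2% of the ceiling, raise an error rather
  than producing a distorted map. Downstream, a refused fit fails that
  subject, not the cohort.
- **Application**: voxelwise lookup with clamping to [0, 1500]; inputs above
  the fitted domain map to 1500.

**One map per acquisition.** Each T2w volume gets its own map, fitted from
reference-structure masks of that acquisition (in the pipeline, the
per-timepoint masks supplied with the data; the baseline's masks serve for
the baseline itself). Because the map is a monotone pointwise function it
commutes with resampling, so a map fitted in the follow-up's native space
applies unchanged to the registered volume. Fitting instead on propagated
baseline masks over the warped volume is supported as a fallback, but
registration error then leaks neighbouring tissue (notably bright
subcutaneous fat next to GM and femur) into the anchor means and biases the
whole map — on phantom cohorts this shifted harmonized tissue values by
~10–15%, which is why per-acquisition reference masks are the default.

## Mask post-processing

Per-slice segmentations stacked into a volume show two artifacts: missing
axial slices and stair-step surfaces. `impute_missing_slices` fills empty
slices strictly inside a structure's occupied range by shape-based
interpolation — linear blending of the neighbouring slices' signed Euclidean
distance maps by slice position, thresholded at zero — which reproduces equal
neighbours exactly and interpolates radii linearly between unequal ones.
`smooth_shape` Gaussian-filters the binary indicator in physical units
(default sigma = in-plane spacing), re-thresholds at 0.5 and keeps the largest
26-connected component. The multi-label wrapper imputes before
connected-component splitting (a missing slice can disconnect a body) and
processes each component separately, so bilateral structures are never
truncated. The exact operators behind the original pipeline's post-processing
are not published; these are standard choices, exposed in the configuration.

## Evaluation metrics

- **DICE** `2|A∩B|/(|A|+|B|)` between automatic (propagated) and manual
  contours; two empty masks score 1 with a warning so batch summaries stay
  finite.
- **Histogram intersection (Minter)** between subjects: 64 equal-width bins
  over the pooled 1st–99th percentile range of each pair, histograms
  normalized per subject, summed bin-wise minima; all C(n, 2) unordered pairs
  with the median reported. The original binning protocol is unpublished;
  this one is fixed here and config-exposed.
- **Histogram equalization** is the comparator normalizer: rank mapping to a
  uniform target on [0, 1500] (exact CDF interpolation, monotone).
- **Repeatability** of mean ROI intensity between the two pre-treatment
  visits, treated as repeat measurements: within-subject SD
  `sw = sqrt(Σ dᵢ² / 2n)` for the paired-duplicate design, repeatability
  coefficient `RC = 2·1.96·sw`, Pearson r (flagged undefined under zero
  variance), and Bland–Altman mean difference with 95% limits of agreement.

## Synthetic phantom

The generator emulates exactly the variability the pipeline must undo, with
analytic ground truth:

- **Anatomy**: ellipsoids on a 96×96×96 mm field of view (default grid
  96×96×48 at 1×1×2 mm) — body with a bright subcutaneous fat rim, bilateral
  GM and femur, bladder, prostate containing a posterior peripheral zone (PZ)
  and a small tumor (GTV) inside it. Containment (GTV ⊂ PZ ⊂ prostate) and
  organ disjointness are validated by boundary sampling before generation.
- **Intensity**: piecewise-constant tissue means placed on the standard scale
  (GM 330, femur 660, bladder 990, fat 1500 a.u.), so the correct
  harmonization map with no scanner distortion is the identity and a gain `g`
  makes it `v → v/g`. Gaussian noise (default SD 15 a.u., ≈5% of the GM–femur
  contrast) approximates the Rician magnitude statistics, which at these
  signal-to-noise ratios differ negligibly.
- **Per-visit distortion**: a monotone scanner transform (gain, offset,
  optional gamma), rigid repositioning (rotation about the volume centre plus
  translation), and a smooth deformation as a sum of Gaussian displacement
  bumps whose summed peak gradient is kept below 0.9 so the warp stays
  invertible. Follow-ups sample the reference anatomy through the analytic
  pull-back map; masks are rendered through the same map and are therefore
  exact. The ground truth exposes the expected rigid recovery, the inverse
  deformation field (computed by fixed-point iteration on analytic bump
  evaluations), and the ideal intensity map.
- **Cohorts**: subject-level anatomy jitter (organ positions/sizes, body
  cross-section, fat-rim thickness 2–6 mm, bladder filling ±18%) and
  independent per-visit scanner gains in [0.6, 1.6] with offsets in [0, 40] —
  longitudinal studies mix magnets and sequences, so each acquisition carries
  its own scale, the baseline included (the baseline's distortion is
  intensity-only; it remains the spatial reference). An optional
  post-treatment effect multiplies chosen tissue means at the post-treatment
  visits (a scale on an ROI covers its contained sub-structures).

What the phantom does **not** model: anatomically realistic texture and
continuous histograms (tissues are constant plateaus, which makes whole-image
histogram equalization look artificially sharp-banded), bias fields, fiducial
or implant artifacts, true Rician noise, and genuine anatomical change other
than smooth deformation and tissue-mean shifts. Passing phantom tests
therefore demonstrates correct mechanics and recovery of known effects under
controlled variability, not clinical-grade accuracy.

## Problem sizes and defaults

Single-pair registration checks run at the native 96×96×48 grid; cohort-level
checks (histogram overlap, repeatability, effect recovery) run at a
64×64×32 / 1.5×1.5×3 mm version of the same anatomy with 2–4 visits and 4–6
subjects per cohort — the package's desk-scale study conditions. The
acceptance script (`scripts/acceptance.py`) regenerates the zero-noise anchor
phantom (reference tissues at 200/500/900, ceiling 1000) from the given seed,
fits and applies the map, and reports the harmonized reference-tissue means
and the output range under adversarial hot-pixel outliers.

## Known limitations

- The refinement has no explicit bending-energy penalty (smoothness comes
  from the control-grid spacing), and its parameters (spacing, dilation
  radius, histogram bins) are this package's defaults, not reproductions of
  the original implementation's unpublished settings.
- Demons stops at shrink factor 2, never full resolution; on coarse grids the
  residual after registration is accordingly larger, and small structures
  (GTV-sized) propagate with visibly lower overlap than the prostate.
- Harmonization assumes the three reference tissues are present, nonempty and
  correctly ordered; severe misregistration of reference masks is caught by
  the anchor-separation guard rather than corrected.
- The cohort pipeline assumes the first manifest timepoint is the reference
  and that the two pre-treatment visits are tagged `baseline` and `planning`.
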