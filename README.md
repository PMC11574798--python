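# reharm

Registration and reference-tissue harmonization for longitudinal T2-weighted
(T2w) prostate MRI.

Serial T2w scans acquired before and after prostate radiotherapy carry two
confounds that block quantitative comparison: anatomy moves and deforms
between visits, and every magnet/sequence combination imposes its own
arbitrary intensity scale. `reharm` removes both:

- **Registration** maps each follow-up onto the baseline scan — a rigid
  pre-alignment, a multi-scale symmetric-forces demons stage (shrink factors
  [4, 2], smoothing sigmas [8, 4] mm), and a mutual-information B-spline
  refinement restricted to the prostate neighbourhood — concatenated by
  composition into one displacement field, so the baseline contours
  (prostate, peripheral zone PZ, tumor GTV) become automatic ROIs at every
  visit.
- **Harmonization** pins the mean intensities of three stable reference
  tissues — gluteus maximus muscle (GM), femur and bladder — to 330, 660 and
  990 a.u., with boundary anchors 0 → 0 and the intensity ceiling → 1500 a.u.
  The anchors are densified piecewise-linearly and fitted with a monotone,
  non-negative P-spline (second-order difference penalty, non-decreasing
  coefficients solved by non-negative least squares); the fit is refused when
  the anchors are inverted or too close ("fit impeded").
- **Evaluation** implements the accompanying statistics: DICE overlap,
  inter-subject histogram intersection (Minter = Σₖ min(h₁ₖ, h₂ₖ)), a
  histogram-equalization comparator, and repeatability of paired visits
  (within-subject SD s_w = √(Σdᵢ²/2n), repeatability coefficient
  RC = 2·1.96·s_w, Pearson r, Bland–Altman limits).

No clinical data is required: a phantom module generates multi-visit
synthetic pelvis volumes with known rigid motion, smooth deformations,
monotone scanner distortions and noise, so every stage can be scored against
analytic ground truth. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from reharm import PhantomSpec, TimepointDistortion, generate_subject, harmonize_volume
from reharm.phantom import structure_mask
from reharm.registration import RegistrationParams, register_longitudinal, warp
from reharm.metrics import dice

# two-visit phantom: the follow-up is shifted 4/-2 mm and rescaled (gain 1.3)
spec = PhantomSpec(
    noise_sd=15.0,
    seed=5,
    distortions=[TimepointDistortion(gain=1.3, offset=20.0, translation=(4.0, -2.0, 0.0))],
)
baseline, followup = generate_subject(spec, n_timepoints=2)

result = register_longitudinal(
    baseline.volume, followup.volume,
    prostate_mask=structure_mask(baseline.mask, "prostate"),
    params=RegistrationParams(seed=1),
)
moved = warp(followup.mask, result.composed_field)
print(f"recovered translation (mm): {np.round(result.rigid.translation_of_center, 2)}")
print(f"prostate DICE after registration: "
      f"{dice(structure_mask(baseline.mask, 'prostate'), structure_mask(moved, 'prostate')):.3f}")
print(f"Jacobian > 0 inside body: {result.qc['jacobian_positive_fraction']:.1%}")

harmonized, imap = harmonize_volume(followup.volume, followup.mask)
print(f"anchors (raw): {np.round(imap.anchors.input_anchors, 1)}")
for tissue, target in [("GM", 330), ("femur", 660), ("bladder", 990)]:
    mean = harmonized.data[followup.mask.binary(tissue)].mean()
    print(f"harmonized {tissue} mean: {mean:.1f} a.u. (reference {target})")
```

Output:

```
recovered translation (mm): [ 4. -2. -0.]
prostate DICE after registration: 1.000
Jacobian > 0 inside body: 100.0%
anchors (raw): [   0.   449.   878.2 1306.8 2003.9]
harmonized GM mean: 330.3 a.u. (reference 330)
harmonized femur mean: 660.0 a.u. (reference 660)
harmonized bladder mean: 989.7 a.u. (reference 990)
```

The injected 4/−2 mm shift is recovered to the printed precision; the
gain-1.3 follow-up (raw GM mean ≈ 449) lands back on the standard scale
within a fraction of a percent of the assigned 330/660/990 a.u.

## Command line

```bash
reharm generate  --out-dir cohort --n-subjects 6 --n-timepoints 2 --seed 7
reharm register  --reference t1.nii.gz --moving t2.nii.gz --out-field field.nii.gz
reharm maskproc  --mask mask.nii.gz --out smoothed.nii.gz --sigma-mm 1.0
reharm harmonize --volume t2w.nii.gz --ref-masks refs.nii.gz --out harm.nii.gz --save-map map.tsv
reharm evaluate  --mask-a manual.nii.gz --mask-b automatic.nii.gz
reharm run       --config config.yaml     # full cohort pipeline
```

`reharm run` consumes a YAML config naming the manifest, output directory and
seed; it writes registered and harmonized volumes, displacement fields,
per-timepoint intensity maps, a longitudinal ROI-mean table
(`longitudinal.tsv`) and a JSON run summary with cohort metrics (pairwise
Minter for raw / harmonized / equalized intensities, repeatability between
the two pre-treatment visits, pre/post percent change of ROI medians) plus
per-subject failure records — a subject that fails any stage never aborts the
cohort.

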