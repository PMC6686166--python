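# stvquant

Semiautomated quantification of **synovial tissue volume (STV)** on
contrast-enhanced, fat-suppressed T1-weighted knee MRI.

Synovitis — inflammation and thickening of the synovial membrane — is common
in knee osteoarthritis and is linked to pain and structural progression.
After gadolinium contrast the synovium enhances, so its volume can be
measured on sagittal CE-MRI stacks; doing that by fully manual slice-by-slice
segmentation takes over an hour per knee. `stvquant` implements the
semiautomated alternative: a statistical model places a loose 3-D mask over
the regions where synovitis occurs, an intensity model classifies the voxels
inside it, scripted edits stand in for the reader's corrections, and the
retained voxels are summed into an absolute volume.

The pipeline has three application steps, with a training stage before them:

1. **Training** (`groupreg`): given training images with loose synovitis
   annotations, a groupwise nonrigid registration (translation + B-spline
   free-form deformation, mean-squares similarity, multiresolution) builds a
   mean reference frame; the training masks are warped into it and averaged
   into a probabilistic *mean 3-D mask*. A PCA over the vectorized
   deformation fields (shape) and over normalized reference-frame intensities
   (appearance) yields the appearance model (`aam`).
2. **Mask propagation** (`aam.fit_aam` / `aam.propagate_mask`): the model
   searches a new image for the mapping from the reference frame — coarse
   exhaustive translation search, then pose + shape coordinate descent — and
   warps the binarized mean mask onto the target, giving a deliberately loose
   L-shaped region of interest.
3. **Targeted thresholding** (`classify`): two whole-image thresholds
   (defaults 25% and 75% of the maximum intensity) define a low- and a
   high-intensity voxel set; each is fitted with a Gaussian N(μ, σ²), and a
   roi voxel is labelled synovitis iff its intensity is more probable under
   the high PDF than under the low one.
4. **Editing and volume** (`workflow`): declarative edit scripts (translate,
   add/remove voxels per slice, re-threshold) replay the reader's manual
   corrections reproducibly; finally
   `STV = voxel_count × dx·dy·dz` (mm³), with dz the centre-to-centre slice
   spacing (3 mm thickness + 0.3 mm gap = 3.3 mm for the default protocol).

Agreement between two measurement routes is quantified in `mcstats`:
Bland–Altman differences with t-based 95% CI of the mean difference and
1.96·SD limits of agreement, two-way mixed-effects consistency ICC(3,1), and
OLS agreement regression (slope ≈ 1 means agreement).

Because clinical trial MRIs cannot be redistributed, the package ships a
phantom generator (`phantom`) producing knee-stack-like volumes: a bright
L-shaped synovium shell of known voxel count, dark background, bright
vessel-like confounders outside the shell, bimodal intensity histogram, and
smooth per-subject deformations — enough structure to exercise and validate
every stage end to end.

## Worked example

```python
from stvquant import (PhantomSpec, generate_cohort, build_mean_frame,
                      train_aam, run_pipeline)

spec = PhantomSpec(seed=100)                      # 64x64x12 @ (0.5, 0.5, 3.3) mm
cohort = generate_cohort(spec, 8, seed=100)       # training subjects
frame = build_mean_frame([c[0] for c in cohort], [c[1] for c in cohort])
model = train_aam(frame, [c[0] for c in cohort])

vol, gt_mask, true_mm3 = generate_cohort(spec, 2, seed=777)[0]  # held out
result = run_pipeline(model, vol)
print(f"estimated {result.volume_mm3:.1f} mm^3, truth {true_mm3:.1f} mm^3")
```

prints

```
estimated 1716.8 mm^3, truth 1716.8 mm^3
```

i.e. the pipeline recovered the planted synovium volume of this held-out
subject to the displayed precision; across ten held-out subjects the error
stays below 1%. The same flow is available from the shell:

```bash
stvquant simulate --out cohort/ --n 8 --seed 100
stvquant build-model --manifest cohort/ground_truth.csv --out model/
stvquant run --model model/ --target cohort/subj000_image.nii.gz --out out/
stvquant evaluate --pairs pairs.csv --out report.json   # Bland-Altman etc.
```

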