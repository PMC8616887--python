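# mandiblo

Automated mandible-shape digitization and morphometric description on
panoramic dental radiographs (orthopantomograms, OPGs).

The mandible remodels throughout life and differs between the sexes, which
makes its shape useful in clinical assessment, dental research, and
forensic identification — but classical morphometric workflows need an
expert to digitize dozens of points per image. `mandiblo` implements a
fully automatic alternative in two steps, plus everything required to
evaluate it:

1. **Contour digitization.** The mandible outline is a normalized closed
   contour of P = 96 points: 8 anatomical landmarks (condyles RC/LC,
   coronoid processes RCP/LCP, gonions RG/LG, superior border SB, inferior
   border/gnathion IB) and 88 arc-length-equispaced semilandmarks.
   Free-form expert annotations are normalized by arc-length resampling
   (*semiautomatic* mode), or a stacked-hourglass convolutional network
   regresses one heatmap per point plus a mandible mask (97 output
   channels) and decodes sub-pixel coordinates with soft-argmax
   (*automatic* mode):

   ⟨x̃, ỹ⟩ = Σₓ Σ_y ⟨x, y⟩ · P(x, y),

   where P is the predicted heatmap normalized to sum 1.

2. **Shape description and estimation.** Contours are superimposed by
   generalized Procrustes analysis (GPA); the deviations from the mean
   shape, ΔX = X − X̄, feed a point distribution model via the singular
   value decomposition ΔX = UΣVᵀ. Mode i explains σᵢ²/Σσⱼ² of the shape
   variance and the model keeps the smallest k reaching a proportion *l*
   (default 0.95). Shapes project to parameters b = (x − X̄)V_k and
   reconstruct as X̄ + bV_kᵀ. Four descriptors — 11 linear
   distances/angles (18 scalars), centroid size √Σ‖pᵢ − centroid‖²,
   shape variations ΔX, and shape parameters b (± centroid size) — drive
   ridge models for sex classification and age regression, evaluated with
   accuracy, per-class F1 = TP/(TP + ½(FP+FN)), MAE, SE and R².
   Digitization quality is scored by point-to-point error, point-to-curve
   error (PT2CRV), and the Dice coefficient of the mandible masks, in mm
   via the acquisition resolution (11.11 px/mm).

Because clinical OPG datasets are not freely redistributable, the package
ships a seeded synthetic cohort generator (mandible-like contours with
logistic size growth, age-driven ramus/chin shape modes, male size
dimorphism, annotation noise, and radiograph-like rendering) so the whole
pipeline is testable end to end. See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
import numpy as np
from mandiblo import (CohortSpec, make_cohort, resample_contour,
                      gpa_align, fit_pdm, build_descriptors, measure,
                      train_test_evaluate)
from mandiblo.descriptors import descriptor_matrix
from mandiblo.estimation import cross_validated_accuracy

# 300 synthetic subjects, ages 5-70, slight male size dimorphism
cohort = make_cohort(CohortSpec(n=300, seed=42))
contours = [resample_contour(a) for a in cohort.annotations]

m = measure(contours[0])
print(f"chin angle a1 = {m.a1:.1f} deg, bigonial breadth d5 = {m.d5:.1f} px")

aligned = gpa_align(contours)
pdm = fit_pdm(aligned, l=0.95)
print(f"PDM keeps k = {pdm.k} modes; mode 1 explains "
      f"{100 * pdm.proportions[0]:.1f}% of shape variance")

X = descriptor_matrix(
    build_descriptors(contours, "shape_params_plus_size", model=pdm))
acc = cross_validated_accuracy(X, np.array(cohort.sexes), seed=0)
print(f"sex classification, 5-fold CV accuracy = {acc:.3f}")

# age regression in the growth years (5-17), where shape tracks age
young = make_cohort(CohortSpec(n=300, seed=43, age_range=(5.0, 17.0)))
cy = [resample_contour(a) for a in young.annotations]
pdm_y = fit_pdm(gpa_align(cy), l=0.95)
Xy = descriptor_matrix(
    build_descriptors(cy, "shape_params_plus_size", model=pdm_y))
_, rep = train_test_evaluate(Xy, young.ages, "age", seed=0)
print(f"age regression: MAE = {rep.mae:.2f} y, SE = {rep.se:.2f}, "
      f"R2 = {rep.r2:.3f}")
```

prints

```
chin angle a1 = 149.7 deg, bigonial breadth d5 = 361.4 px
PDM keeps k = 3 modes; mode 1 explains 90.6% of shape variance
sex classification, 5-fold CV accuracy = 0.670
age regression: MAE = 0.98 y, SE = 1.17, R2 = 0.897
```

The first mode captures the dominant growth-driven shape change (ramus
opening in the young, chin protrusion with age); combining the size-free
shape parameters with centroid size lets the classifier separate the
sexes' size difference from the age-driven growth that confounds size
alone, and lets the regressor read age off the growth signal.

The same pipeline is scriptable from the shell:

```sh
mandiblo simulate --n 50 --seed 3 --out data/
mandiblo train --images data/images --annotations data/annotations --out model/
mandiblo predict --model model/ --image data/images/subj0000.png --out contour.csv
mandiblo estimate --task sex --data data/ --out sex_report.json
mandiblo evaluate --ref data/contours --est predicted/ --spacing 11.11 --out quality.json
```

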