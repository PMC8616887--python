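# Methods

## Overview

`mandiblo` implements a two-step pipeline for quantitative mandible-shape
analysis on panoramic radiographs (orthopantomograms, OPGs):

1. **Digitization** — locate a normalized 96-point mandible contour on the
   image, either *semiautomatically* (resampling a free-form expert
   annotation) or *automatically* (heatmap-regression CNN with soft-argmax
   decoding).
2. **Description** — summarize the contour with four descriptors: linear
   distances/angles, centroid size, Procrustes shape variations, and
   point-distribution-model (PDM) shape parameters; use them in ridge
   models for sex classification and age regression.

## The contour scheme

The contour is a single closed loop through eight anatomical landmarks —
condyles (RC, LC), coronoid processes (RCP, LCP), gonions (RG, LG),
superior/interdental border (SB) and inferior border/gnathion (IB) — with
a fixed number of semilandmarks per segment: 8 on each
condyle–gonion segment, 8 on each gonion–IB segment, 10 on each
condyle–coronoid segment, and 18 on each coronoid–SB segment, for
88 semilandmarks and 96 points total. The traversal order is
RC→RG→IB→LG→LC→LCP→SB→RCP→(RC): lower border first, then the superior
margin, chosen so the polygon is a simple closed loop for rasterization.
"Right"/"left" are anatomical; the patient's right appears on the image's
left.

Free-form annotations (arbitrary point counts per segment) are normalized
by arc-length parameterization of each segment's polyline (landmark, raw
clicks, landmark) and placing the scheme's semilandmark count at equal
arc-length fractions strictly between the endpoint landmarks. Equal
spacing is by arc length, not chord length, and no bending-energy sliding
is applied — semilandmark identity is positional only. A segment whose
polyline has zero length (coincident endpoints, no distinct clicks)
is an error rather than a silent duplication.

Coordinates are (x, y) floats, origin at the top-left pixel center,
x rightward, y downward, 0-based.

## Automatic digitization

Landmark localization is posed as heatmap regression. Targets are
isotropic bivariate normal densities (peak 1) centered on each contour
point, with standard deviation `sigma_frac × image width` so the encoding
behaves identically across resolutions; `sigma_frac` defaults to 0.01 and
is configurable. A 97th channel carries the filled mandible mask.

The network is a stacked hourglass: a convolutional stem followed by
`stacks` hourglass modules (recursive pool → residual blocks → nearest
upsample, with a residual skip at every scale), each emitting a
97-channel prediction at input resolution; intermediate supervision
applies the loss to every stack, and each stack's features and beliefs
are remapped into the next. Before each prediction a widening 1×1
convolution + ReLU lifts the feature width to at least the output
channel count — a 1×1 prediction straight from c features caps the
97-map stack at rank c + 1, which at tiny widths forces the maps to
smear along the contour instead of peaking. The reference configuration
is 256×512 input, depth 4, 64 initial filters; tests and the acceptance
run use tiny configurations (e.g. 64×128, depth 2, 12 filters, 1 stack),
a problem size chosen so the full suite runs in minutes on one CPU core.
The implementation is a self-contained numpy engine (im2col convolutions
with hand-written backward passes, float32, Adam), fully deterministic
given the config seed.

Training minimizes per-pixel mean squared error between predicted and
target stacks with Adam; loss/optimizer are this package's choices,
standard for hourglass-style heatmap regression. Three details matter in
practice. The mask channel carries roughly 35× more energy than a point
map, so the point channels are up-weighted in the loss
(`point_loss_weight`, default 10) to keep the peaks in the gradient.
The 1×1 prediction layers are zero-initialized: a He-initialized deep
stack otherwise starts with enormous random maps whose first optimizer
steps drive the post-hourglass ReLUs into a dead, predict-constant fixed
point. And the learning rate ramps linearly over the first 10% of steps
(`warmup_fraction`). A seeded 85/15 split selects the epoch with the
lowest validation loss (fewer than seven pairs: training loss); with
very few images the batch size should be small (batch 1 on a 4-image
set), since steps per epoch, not epochs, set the optimization budget.

Decoding: each predicted point map is rectified, normalized to sum 1, and
reduced by soft-argmax — the probability-weighted mean of pixel
coordinates, a sub-pixel, differentiable approximation of the peak.
Rectification clamps negatives to zero; at predict time a configurable
fraction of the map maximum (`threshold_frac`, default 0.1) is subtracted
first. For a map symmetric about its peak this leaves the decoded
coordinate unchanged (the Gaussian-target round trip stays exact), but it
removes the center bias that diffuse low-level background in a *learned*
map would otherwise inject into a global expectation. A map with no
positive mass flags its point (placed at the map center) rather than
failing the whole contour. The mask channel participates in the loss but
not in decoding. Decoded coordinates are mapped back to the original
image by the inverse pixel-center rescale.

## Shape modeling

Generalized Procrustes analysis (GPA) centers each shape, scales it to
unit centroid size, and iteratively rotates it onto the running mean
(orthogonal Procrustes restricted to det +1 — a reflected mandible is
anatomically distinct) until the mean changes by less than `tol = 1e-10`
(max 100 iterations). The Procrustes rotation is invariant to the
reference's scale, so the plain sample mean serves as the reference and
the stored mean equals the sample mean of the aligned rows exactly,
making the deviations ΔX = X − X̄ exactly column-centered. Alignment
includes scaling because the shape descriptors are deliberately
size-free; size is carried separately as centroid size
(√Σᵢ‖pᵢ − centroid‖²).

The PDM is the SVD of the n × 192 deviation matrix, ΔX = UΣVᵀ. Mode i
explains the proportion σᵢ²/Σⱼσⱼ² of total shape variance (the 1/(n−1)
covariance factor cancels in proportions); the retained mode count k is
the smallest k whose cumulative proportion reaches the threshold `l`
(default 0.95; `l = 1` keeps the full numerical rank, singular values
above 1e-9 of the largest). Mode signs are fixed so each mode's
largest-magnitude component is positive, making results stable across
SVD implementations. Shapes project as b = (x − X̄)V_k after being
aligned into the model frame (center, unit size, rotation onto X̄) and
reconstruct as X̄ + bV_kᵀ.

One second-order caveat: the sample mean of unit-size shapes is itself
slightly smaller than unit size, so re-aligning X̄ as if it were a new
shape leaves a residual of order the squared shape dispersion (~1e-5
here). Projection of the mean *in the model frame* is exactly zero.

Group visualization reconstructs each group's mean first-mode score with
k = 1 and optionally rescales by the group's mean centroid size,
separating the pure-shape from the shape-plus-size contrast.

## Descriptors

* **Measurements** — 18 scalars for 11 codes (bilateral codes carry
  separate left/right values): chin angle a1 at IB between the rays to
  the gonions; mandibular angle a2 between total-least-squares lines
  through the posterior-ramus and lower-body-margin semilandmarks
  (endpoints included; a two-point chord fallback is available), oriented
  away from the gonion; coronoid–condylar angle a3 at the gonion;
  distances d1 (gonion–IB), d2 (gonion–condyle), d3 (gonion–coronoid),
  d4 (bicondylar), d5 (bigonial), d8 (SB–IB, straight distance); and
  vertical distances d6, d7 as absolute image-frame y differences (OPGs
  are acquired upright). Distances are reported in mm when pixel spacing
  is known (the reference acquisition device resolves 11.11 px/mm),
  otherwise in px; angles are interior angles in degrees.
* **Centroid size** — computed on the unaligned contour, so it keeps
  original units.
* **Shape variations** — the aligned shape minus the mean (length 192).
* **Shape parameters** — the k PDM scores, optionally concatenated with
  centroid size.

## Estimation

Ridge regularization addresses the strong collinearity among mandible
features. Classification is a ridge-penalized linear model on ±1 sex
labels with a sign decision at 0; regression predicts age in years.
Features are standardized; the penalty is selected by seeded 5-fold CV
(stratified for sex) over 13 log-spaced values in 1e-3…1e3, maximizing
fold accuracy (sex) or minimizing fold MSE (age). Evaluation uses a
seeded stratified 80/20 train/test split, or k-fold cross-validation for
the cohort-level accuracy helper. Reports: accuracy and per-class F1
(TP/(TP + (FP+FN)/2)) for sex; MAE ± SD of absolute error, residual
standard error SE = √(SSres/(n−2)), and R² = 1 − SSres/SStot for age.
Sex estimation is most meaningful in adults and age estimation in the
growth years, so the pipeline accepts optional age-range filters per
task.

## Digitization quality metrics

Point-to-point error is the Euclidean distance between matching named
landmarks; the point-to-curve error (PT2CRV) is the mean over the 96
estimated points of the minimum distance to the *closed polyline* through
the reference points (a directed, asymmetric quantity); mask agreement is
the Dice coefficient 2|A∩B|/(|A|+|B|) (defined 1 when both masks are
empty). Pixel distances convert to mm by division with the px/mm spacing.
Cohort reports additionally average bilateral measurement errors over
sides.

## Synthetic cohorts

The generator exists so every stage is testable without clinical data. A
hand-designed, bilaterally symmetric 96-point template (256×512 frame,
built from spline control points and normalized by the same resampler as
real annotations) is deformed per subject:

* **Size** follows a logistic growth curve in age (floor 0.55 of adult
  size, midpoint 11 y, scale 3.5 y), saturating near adulthood;
  males are scaled by a dimorphism factor (default 1.06 — a slight size
  advantage); individuals get lognormal size jitter (σ = 0.04).
* **Shape** has two age-driven modes along the same maturity curve as
  size — ramus opening (young subjects' rami are splayed outward; default
  8° at the youngest age, implemented as a smooth rotation about each
  gonion weighted by height above it) and chin pointiness (older
  subjects; default 6 px downward displacement around IB) — plus
  independent per-subject jitter on both (1.5° / 1.5 px), so the shape
  space is not a degenerate one-dimensional curve.
* **Annotation** adds isotropic Gaussian noise per point (default
  0.4 px at the 256-px frame, matching the order of the reported
  interobserver point-to-curve error of ~0.2 mm once scaled from the
  ~1552-px clinical resolution) and re-expresses the contour as a
  free-form annotation: per segment, a random number (12–30) of roughly
  evenly spread clicks along the noisy polyline. The resulting
  matched-point discrepancy after renormalization is dominated by
  tangential sliding — semilandmarks have no along-curve identity —
  while the perpendicular (point-to-curve) recovery error stays near
  0.1 px.
* **Rendering** fills the contour polygon, blurs the edge (σ 1.5 px),
  and adds patient-specific smooth texture at two spatial scales plus
  pixel noise, intensities in [0, 1]. The texture is deliberately
  visible (~0.1 amplitude): real radiographs carry local structure, and
  a texture-free render would make every point along a smooth edge
  locally indistinguishable — an aperture problem no localizer could
  overcome.

Ages are uniform over the configured range (default 5–70) and sexes
follow the configured ratio. All randomness flows from one seeded
generator; no global state.

What the generator does **not** emulate: teeth and their superposition,
the spine shadow and device-specific panoramic distortions, correlated
(structured) annotation error, asymmetry, population heterogeneity
beyond the two shape modes, and sex differences in *shape* (dimorphism
is deliberately size-only). Passing tests therefore demonstrate the
correctness and internal consistency of the machinery — not clinical
performance on real OPGs, which depends on a trained full-scale network
and real population variation.

## Numerical and design choices

* Rasterization counts a pixel as inside when its center is inside *or
  on* the polygon (shapely); self-intersecting polygons fall back to an
  even-odd crossing-number fill with a warning.
* Degenerate inputs fail loudly and specifically: missing landmarks and
  zero-length segments are named; zero-size shapes name the offending
  index; all-zero heatmaps raise unless reached through the
  flag-and-continue predict path.
* GPA is deterministic given input order; its output is defined up to a
  global rotation (comparisons use Procrustes distance).
* The network uses average pooling (smooth gradients at tiny scales) and
  nearest-neighbor upsampling; He initialization from the config seed.
* The overfit-based end-to-end checks train a tiny network (64×128,
  depth 2, 1 stack, 12 filters, 200 epochs at batch size 1, σ fraction
  0.03) on four images — a problem size that keeps the check
  minutes-scale on one CPU while still exercising the full
  train/predict/describe path; it reaches ~0.1 px point-to-curve and
  ~0.3 px matched-point error on its training images.

## Known limitations

* The numpy network is CPU-bound and intended for small configurations;
  full-scale training (256×512, depth 4, 64 filters, hundreds of images)
  is out of its practical range.
* Global soft-argmax assumes a unimodal rectified map; multimodal
  predictions decode to a mass-weighted compromise (mitigated but not
  eliminated by the decode threshold).
* Measurements assume the image frame's vertical axis for "height"
  codes; rotated acquisitions would need prior standardization.
* Ridge models are linear; strongly nonlinear age–shape relations are
  captured only through the descriptors themselves.
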