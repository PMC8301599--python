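# Methods

## Problem and model

`echolv` predicts the position of the murine left-ventricular (LV) wall —
both the endocardial and epicardial boundaries — from 4D high-frequency
ultrasound cine data.  Rather than segmenting pixels, the wall is
parameterized by 48 *anchor points*: the radius from the central long axis
at six rotations θ ∈ {30, 90, 150, 210, 270, 330}° (counterclockwise from
+x; the septum lies on −x), on two boundaries b ∈ {endo, epi}, at four
short-axis levels z ∈ {25, 50, 75, 100} % of the apex-to-base distance.
Apex and base axial positions are tracked per frame and slice levels are
fractions of the *current* apex-to-base distance, which compensates
through-plane motion.

For each anchor (θ, b, z) the radius over the cycle is a linear model fit by
ordinary least squares:

    ŷ_{θ,b,z}(t) = W_k β_{θ,b,z} + Φ(t) γ_{θ,b,z}          (variants 1, 2)
    ŷ_{θ,b,z}(t) = W_k β_{θ,b,z} + Φ(t) γ_{θ,b,z} + δ μ     (variant 3)

where `W_k` are scores of the short-axis images on the leading k principal
components (variant 1: one PCA subspace per slice level, each anchor using
its own slice's scores; variants 2–3: one joint PCA of the concatenated
four-slice pixel vector), `Φ(t)` is a periodic cubic B-spline basis over
cycle phase, and μ is a single user-supplied annotation: the true radius of
one chosen *assist anchor* (default: endocardial, θ = 90°, z = 0.50) at
end-diastole for the dataset being predicted.  δ is one extra scalar fit
jointly with β and γ.  Since murine hearts differ from one another mostly in
overall size, the single annotated radius largely resolves the per-animal
size offset that otherwise dominates prediction error.

Numerical choices:

* The spline basis is an *unpenalized* periodic cubic B-spline expansion on
  uniform knots, default 8 basis functions.  It is a partition of unity, so
  it spans constants and no intercept column is added.  Periodicity (value
  and first-derivative continuity at phase 0 ≡ 1) reflects the periodicity
  of the cardiac cycle.
* One shared k is used for all 48 anchors of a fitted model; the
  cross-validation harness selects k per permutation on the validation set
  (smallest k on ties).
* Rank-deficient or under-determined designs fall back to the minimum-norm
  least-squares solution (`numpy.linalg.lstsq`), with a logged warning.
* PCA is always refit on the training animals of the current permutation;
  validation/test images never enter the decomposition.
* Images enter the PCA as raw vectorized intensities (no per-image
  normalization, no downsampling by default; both are configuration
  choices).

## Mesh construction

Anchor radii are interpolated to a standardized 4D sampling of each
boundary surface: 60 rotations × 60 apex-to-base levels × 60 uniform cycle
positions.  Interpolation is separable and ordered θ → z → t:

1. **θ**: a closed periodic interpolating cubic spline through the six
   radii of each (slice, frame); reproduces a circle exactly.  An optional
   engine (`engine="hobby"`) uses a tension-based cubic-Bézier construction
   with Hobby's control-handle velocity function and chord-bisector
   tangents; both engines interpolate the anchors exactly and are C1-closed.
2. **z**: a natural cubic spline through the four slice levels, extended by
   an apex point with radius 0 at level 0.  The basal end is left open.
   The z samples are (0, 1] in steps of 1/60, excluding the singular apex
   point itself.  The apex closure is a modeling choice that only affects
   volumes and longitudinal lengths near the apex.
3. **t**: a periodic cubic spline across the cycle, resampled to 60 uniform
   phases (apex/base tracks are resampled the same way).

The mesh *interpolates*: at every anchor coordinate it reproduces the input
radius to ≤ 1e-6 mm, and doubling the output resolution changes contour
perimeters by < 0.5 %.

## Kinematics

Strain is Lagrangian (engineering) strain against the end-diastolic
reference (phase 0): circumferential strain from closed-contour perimeters
at fixed z, longitudinal strain from 3D apex-to-base surface-curve lengths
at fixed θ (including per-frame apex/base motion).  Windowed strain *rates*
(1/s) are OLS slopes of strain vs time within four windows: systole
[0, ps] and diastole [ps, 1], each split at its midpoint into early/late
halves.  The peak-systole phase ps is located globally at the endocardial
cavity-volume minimum, so all curves share one landmark.  The diastolic
windows include the wrap-around sample (phase 1 carries the phase-0 strain,
which is 0 by definition).  The early/late window convention is this
package's own definition — the field uses several — and early diastolic
strain rate is known to be the most sensitive metric to it.

Cavity volume is the trapezoidal sum over z of the shoelace polygon area of
each 60-point contour, with a zero-area apex point; EDV is the volume at
phase 0, PSV the minimum over phases (earliest on ties), SV = EDV − PSV,
EF = 100·SV/EDV.  On a straight-walled cylinder the polygon and
apex-closure discretizations together bias volume by about −1 % (bounded,
documented; the EF of a uniformly scaled mesh is exact because the bias
cancels in the ratio).

The standard metric table holds peak strain plus the four strain rates at
3 circumferential levels (basal, mid-LV, apical) and 6 rotations, plus the
4 global metrics: 49 rows.  (The reference analysis this package follows
reports "80 metrics" without an enumeration that matches this contract —
possibly both boundaries were included; the table here is configurable per
boundary and the discrepancy is deliberately left visible rather than
guessed away.)

## Evaluation protocol

Monte Carlo cross-validation: whole animals are split 6:1:1 into
train/validation/test (validation and test each receive ⌊n/8⌋ animals),
independently per iteration with seed `base_seed + iteration`.  Per anchor,
test MSE (mm²) and R² (SST about the per-anchor test mean) are recorded.
Model comparison uses paired two-sided t-tests on per-observation squared
errors within each (iteration, anchor) cell, with "significantly better"
requiring p < 0.05 *and* a lower mean; the percent of significant cells is
aggregated over anchors and iterations.  Per-boundary MSE aggregates a
boundary's 24 anchors by their mean; the model-ordering fraction counts
iterations whose mean-across-anchors MSE is monotone M3 ≤ M2 ≤ M1.
Ground-truth vs predicted metric tables are compared per metric by paired
t-tests with a Bonferroni correction (adjusted p = min(1, p·n_metrics),
flagged at adjusted p < 0.001).  The paired unit throughout is one
(animal, frame) observation.

## The phantom

Real murine 4DUS cohorts are not freely available, so the package ships a
synthetic beating-LV phantom that defines the study conditions for every
test.  The endocardial radius field is analytic:

    r_endo(θ, zf, t) = r_ed · √(zf (2 − zf)) · (1 − amp(θ, zf) · g(t))

with g a raised-cosine contraction bump (g(0) = 0 at end-diastole,
g(ps) = 1 at peak systole, C1 at the cycle wrap; ps = 0.35 by default) and
per-animal regional amplitudes amp varying smoothly in θ and z (first
harmonic + linear z trend, coefficients drawn once per animal with SD 0.08
around a 25 % peak contraction).  The epicardium is the endocardium plus a
wall thickness that thickens 35 % at peak systole from 0.8 mm at
end-diastole.  Per-animal basal endocardial radii are normal with mean
1.6 mm, SD 0.2 mm — the size offsets the assisted model exploits.  Default
timing: 32 frames/cycle at 500 bpm; default imaging: 128 px at
0.06 mm/px, 16 stored slices spanning a 5.5 mm apex-to-base axis with
0.8 mm basal descent at systole.

Images are rendered from the same analytic field that defines the
ground-truth anchor radii, so truth and images are exactly consistent.
Murine cardiac ultrasound is dominated by speckle and shows low tissue
contrast; the phantom emulates this with a bright-but-low-contrast wall
(wall 0.5 vs background 0.25, cavity 0.12) under strong multiplicative
unit-mean Rayleigh speckle (blend weight 0.8), plus an attenuated
posterior-septal shadow sector (center 210°, extent 60°, attenuation 0.4)
on basal slices, emulating the sternum shadow.  The speckle model is a
configuration choice, not a claim about ultrasound physics; papillary
muscles, attenuation physics and point-spread functions are out of scope.

What passing tests on the phantom do and do not show: the phantom's
kinematics live on a low-dimensional latent space (size + 3 regional
coefficients), its images are perfectly centered and its appearance is
stationary across animals, so absolute accuracies (R² ≈ 0.88–0.98) are far
higher than on real data and should be read only as *relative* statements
about the three variants and as self-consistency checks of the pipeline.

A second, degenerate generator (`generate_model_family_cohort`) draws
images with exact rank-k variation and radii exactly linear in the image
weights plus a spline trend — inside the regression model family — for
parameter-recovery checks (noiseless fits must reach R² > 0.99 / MSE below
1e-6 mm²) and, with images replaced by pure noise, for the no-signal null
(R² ≈ 0).  The null is run on this cohort rather than the phantom because
on the phantom the spline basis alone legitimately explains the shared
contraction waveform, so R² against a constant baseline stays high even
without any image signal.

## Problem sizes used by the shipped checks

The test suite exercises the CV-heavy properties on a 16-animal, 64 px,
15-iteration cohort and miscellaneous modules on an 8-animal, 48 px
phantom; `scripts/acceptance.py` runs the full protocol at 24 animals,
128 px, 20 Monte Carlo iterations with k selected from {2, 4, 8, 12}.
These sizes are the package's chosen desk-scale defaults; all of them are
configuration, not constants.

## Known limitations

* The rigid reorientation to the standard axes is user-supplied (real
  acquisitions are manually aligned); no automatic long-axis detection.
* Apex/base tracks are treated as input data; no tracking algorithm is
  provided.
* The per-iteration ordering M3 ≤ M2 ≤ M1 is a stochastic property: it
  holds in the large majority of Monte Carlo iterations under the default
  phantom, but individual iterations can favour model 2 when the test
  animals' sizes happen to be well predicted from images alone.
* Early diastolic strain rate depends strongly on the early/late window
  convention and is the least robust metric in the table.
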