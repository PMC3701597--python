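# Methods

This note documents the models, algorithms and numerical choices behind
`fincam`, module by module, together with what the synthetic data do and
do not emulate.

## Synthetic chamber video

Fish are rendered as filled silhouettes: the body is a tapered ellipse
(depth profile `half_depth * (1 - (2s-1)^2)^(0.85/2)` along the
normalized body axis `s`), and fins are polygons attached at anchor
positions — triangular dorsal and anal fins, a small adipose bump, a
forked caudal fin extending past the body, and for the threadfin shad a
thin trailing filament over the caudal peduncle. The rasterized union
is morphologically closed so every silhouette is a single 8-connected
component. This reflects the physical instrument, whose even backlight
reduces passing fish to high-contrast silhouettes in which fin detail
is the species cue.

Default species (pixel sizes at the scaled-down 300 x 400 test frame;
the native sensor is 1200 x 1600 at 60 fps, so multiply by ~4 for
native-scale fish):

| species | body length (px) | aspect | distinguishing fins |
|---|---|---|---|
| delta_smelt | 60 | 4.6 | adipose fin present |
| threadfin_shad | 55 | 2.7 | dorsal-fin thread over the peduncle |
| american_shad | 75 | 3.3 | plain dorsal/anal/caudal |

No published size-in-pixels statistics exist for fish inside the
chamber, so these defaults were chosen once for silhouette
separability at test resolution, not for morphometric realism.

**Turbidity model.** Foreground/background contrast is multiplied by
`exp(-c * NTU)` with `c = 0.04` per NTU, and Gaussian sensor noise
grows linearly as `sd = noise_sd + 0.15 * NTU` gray levels. The single
constant `c` is calibrated so that detection recall on the default
species collapses below 50% near 80 NTU — the operating point where
the real system degrades — while scenes at 30 NTU and below remain
easy. A fish at 200 gray over a 40-gray background therefore has edge
contrast 160 at 0 NTU, ~48 at 30 NTU and ~6.5 at 80 NTU, by which
point the noise floor (~14 gray SD) swamps it.

Scenes are fully determined by their `SceneSpec` including the seed;
rendering the same spec twice yields bit-identical frames. Ground
truth records, per fish, every frame its mask intersects and the
realized mask centroid, so downstream stages can be scored exactly.

Limitations: straight-line trajectories with constant orientation, no
3-D pose, no occlusion between fish, no backscatter or lighting
gradients. Passing vision tests on these scenes demonstrates the
algorithm chain is correct under its stated assumptions
(non-overlapping motion, moderate turbidity); it does not measure
performance on overlapping or manoeuvring fish.

## Detection and tracking

The gradient-contour chain is: per-pixel temporal-median background
(an evenly spaced sample of up to 31 frames), background subtraction,
Gaussian pre-smoothing (sigma = 1 px), 3x3 central-difference gradient
magnitude, hysteresis thresholding (high = 12 gray/px by default,
low = high/2), morphological closing (disk radius 2), hole filling,
then an erosion (disk radius 2) that removes the outward half of the
smoothed edge band so component areas match the underlying silhouette,
and finally 8-connected component labeling with area gating
(default 150 to frame_area/4 px).

Numerical notes: the pre-smoothing exists because raw pixel noise
percolates the low hysteresis threshold into frame-sized components;
the erosion compensates the ~2.4 px outward extent of the smoothed
edge band. Two objects closer than ~9 px merge (band + closing reach);
partially entered fish whose edge ring is cut by the frame border do
not fill and are dropped by the area gate until mostly inside — this
is why the minimum area default exceeds the largest entry sliver.

Tracking is greedy nearest-neighbour association on a
constant-velocity prediction, gated at 60 px (a fish crossing the
frame width in ~0.5 s at 60 fps), with up to 2 missed frames bridged
and tracks shorter than 3 detections discarded as noise. Ties are
broken by smallest predicted distance, then lowest track id. Each
surviving track is one counted passage; a gap longer than the
tolerance splits a passage into two tracks and is a documented
over-count mode.

## Shape features

All descriptors are computed from the binary (or anti-aliased) mask:

* **area** in pixels (the chamber geometry is fixed, so pixel size is a
  consistent proxy for body size; no mm calibration).
* **Hu moments**: the seven invariants of the normalized central
  moments, reported as `sign(h) * log10(|h| + 1e-30)` to compress
  their dynamic range for the SVM while keeping the sign (the seventh
  carries chirality).
* **aspect ratio**: major/minor axis of the inertia-equivalent
  ellipse, always >= 1.
* **ellipse defect**: area of the symmetric difference between the
  mask and its moment-fitted ellipse (same centroid, orientation and
  axis ratio, rescaled to equal area), divided by mask area; 0 for a
  true ellipse, in [0, 2].
* **template RMS**: the object is brought to a canonical 64 x 128
  frame — crop to the mask bbox, rotate the major axis horizontal,
  flip head-left by the sign of the column skewness, resample,
  normalize to zero mean and unit variance over the frame — and
  compared to each species template by root-mean-square difference.
  The residual mirror ambiguities (near-zero skew; the 180-degree
  major-axis ambiguity) are resolved by taking the smallest RMS over
  the four axis reflections.
* **radial local pattern**: the centroid-to-boundary distance sampled
  by ray-marching (0.25 px steps, bilinear mask interpolation) at B=32
  angles starting from the major axis, divided by the mean radius.
  This is a standard rotation-normalized radial signature; the
  published description names the feature without defining it, so this
  concrete form is a reconstruction.

Invariance in practice: translation is exact to floating-point; under
anti-aliased rotation the Hu values move by < 1e-2 (log scale) for
bodies ~180 px long, and under resampling to other scales by < 0.05.
Rasterization error grows as bodies shrink below ~100 px, which is why
invariance properties are stated at native-like resolution.

## Species identification

An RBF-kernel SVM (C = 10, gamma = 'scale') on standardized features,
with pairwise-coupling (Platt) probability calibration supplying the
per-object confidence — the published system reports "a level of
confidence" without an algorithm, so calibrated class probabilities
are the reconstruction; human-assigned confidences are carried as an
optional override column, not modelled. Training requires >= 2 classes
with >= 3 examples each; feature scaling is fitted on training data
only and travels with the model.

Two cross-validation protocols are provided: the conventional k-fold,
and the inverted protocol in which each 1/k subset is the *training*
set and the remaining (k-1)/k are scored — the protocol described for
small hand-curated image libraries. Folds are stratified by label
where possible and seeded; a fold whose training subset cannot be
trained is skipped with a warning and reported.

## Trawl pipeline

A sample is one 10-minute tow at one cell of the 2^3 design: tide
(flood/ebb), horizontal position (center/side), vertical stratum
(upper/lower). A track belongs to a sample if its *first* detection
time falls in the half-open window [start, end) — water filtered
during descent and retrieval is not part of the sample — and counts
can be restricted to identifications at or above a confidence cutoff
(1.0 by default, matching the practice of analysing only
full-confidence identifications; the 1.0/0.9/0.04 sweep is supported).
Density is `count / volume_m3 * 10,000`. Stratum assignment compares
the median deployment depth with half the water depth; an exactly
mid-depth tow counts as lower (tie rule). Survival is
`round(100 * passed / (passed + entangled))`; entangled counts are an
external input because the timing of entanglement is unobservable.

## Count models

Counts per tow are modelled on the log scale with `log(volume)` as an
offset, so coefficients describe density. Treatment coding uses
reference levels ebb/center/upper; the tide coefficient is therefore
the flood effect. The nested formulas are main effects (H+V+T, 4
columns), + two-way interactions (7), + the three-way term (8); an
intercept-only formula is available for degenerate designs, and
factors constant in a dataset are dropped (with their interactions)
rather than producing a rank-deficient matrix.

* **Poisson**: Newton/IRLS on the exact log-likelihood; converged when
  the score norm < 1e-8; steps are damped and escaping coefficients
  (all-zero counts) are flagged, never silently returned.
* **Quasi-Poisson**: the Poisson mean fit with Pearson dispersion
  `phi = X^2/(n-p)` (the standard estimator), standard errors scaled
  by sqrt(phi), Wald tests against t with n-p df. No likelihood, hence
  no AIC: quasi-AIC surrogates compare only quasi-Poisson models and
  are excluded from cross-family ranking.
* **Negative binomial (NB2)**: joint MLE of (beta, log theta) by
  L-BFGS-B with analytic gradients; variance `mu(1 + mu/theta)`; the
  conventionally reported multiplier is 1/theta. Theta is bounded
  above at 1e4; hitting the cap (or theta >= 100) flags the data as
  Poisson-like. Standard errors come from the observed information
  (central-difference Hessian of the analytic gradient).
* **ZINB**: the mixture `pi * I{y=0} + (1-pi) * NB2` with an
  intercept-only logit for pi — a single zero-inflation probability
  across treatments, the reading consistent with one reported pi for
  all three formula sets. Maximized by L-BFGS-B with analytic
  gradients from three starts (the NB solution plus the logit of the
  empirical excess-zero fraction, and two perturbed starts); gradient
  tolerance 1e-8. Total zero probability is
  `pi + (1-pi) (theta/(theta+mu))^theta`. Data with no zeros drive
  pi to 0 (flagged); all-zero data are rejected as unidentifiable.

AIC = 2k - 2 logL with k counting every estimated parameter (beta,
plus theta, plus gamma). Ranking flags AIC differences of 2 or less as
negligible, preferring the simpler model. The dispersion diagnostic
exposes (y-mu)^2 against mu to distinguish the linear quasi-Poisson
variance from the quadratic NB form; note that for small theta the
fourth moment makes this scatter extremely noisy, so curvature is only
reliably detectable with wide mu ranges and thousands of observations.

The simulator draws Poisson, gamma-Poisson (NB) or zero-inflated NB
counts from a known truth on any factor table, seeded, and is the
oracle for all recovery tests (at n = 2000: beta within 3 SE, theta
within 25-30%, pi recovered inside [0.5, 0.7] for truth 0.6).

## Power analysis

`power_pairwise` is the exact two-sample t-test power via the
noncentral t: ncp = delta/(sd sqrt(2/n)), df = 2n-2. The one-sided
test is the default because it reproduces the published design values
(79% at delta 3, 95% at delta 4 for n = 7, sd = 2.1), whereas the
two-sided version gives ~69%/90%; the choice is exposed as a flag. A
seeded Monte-Carlo mode (200,000 replicates agree with the analytic
value within 0.005) provides the independent check.

`power_factorial` is a seeded Monte-Carlo power of the global F-test
(full cell-means model vs grand mean) for arbitrary cell-mean
configurations of the 2^3 design. The exact procedure behind the
published global-test power claim for this design is not stated and a
global F-test does not reproduce it from the stated inputs, so the
function is provided as machinery — its size at the null and its
agreement across independent seeds are what the tests assert.

## Problem sizes used in tests

The suite runs on 300 x 400 frames (the native 1200 x 1600 geometry is
supported but four times larger in every linear dimension), 20
two-species scenes of 72 frames for the end-to-end checks, training
libraries of 100 silhouettes per species, n = 2000 datasets for
parameter recovery, 100 replicates at n ~ 500 for the bias suite, and
200,000 Monte-Carlo replicates for power. These sizes keep the full
suite around a minute while leaving every statistical check at least
3 standard errors of headroom.

## Known limitations

* The vision chain assumes non-overlapping fish; merged silhouettes
  are detected as one object (a documented under-count mode), and
  trailing appendages entering the frame ahead of their attachment can
  transiently appear as separate blobs (suppressed by the area gate).
* Species templates are one reference image per species; multiple
  reference poses per species would be a straightforward extension.
* Feature invariances degrade below ~100 px body length; at the
  scaled-down test geometry the classifier compensates through
  training-time jitter.
* The ZINB zero model is intercept-only by design; covariate-dependent
  zero inflation is out of scope.
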