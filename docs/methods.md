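# Methods

## Overview

`siribruise` implements a structured-illumination reflectance imaging
(SIRI) analysis chain for detecting subsurface bruises in fruit.  A
sinusoidal fringe pattern of spatial frequency `f` (cycles/m) is projected
onto the sample and imaged at three phase offsets (−2π/3, 0, +2π/3).
Per-pixel three-phase demodulation separates a planar component
(DC — equivalent to uniform illumination) from the modulated amplitude
(AC), whose depth of interrogation shrinks as `f` grows; a shallow bruise
therefore appears as an AC deficit while remaining invisible in DC.  The
ratio image RT = AC/DC cancels illumination nonuniformity (surface
curvature, reflectance) and is the preferred detection image.  Detection
proceeds by Otsu segmentation of the bruise, a contrast-index (CI) sweep
to pick the operating frequency, 56 GLCM Haralick texture features per
masked image, random-frog feature selection, and LS-SVM / PLS-DA / KNN
classification of sound versus bruised fruit under repeated stratified
7:3 splits.

Because no public image corpus accompanies this problem, the package
ships a first-class synthetic-scene generator whose phantoms carry full
ground truth; every quantitative claim made by the test suite refers to
these phantoms.

## Synthetic scenes

A phantom is a bright ellipse (the fruit) on a dark background in a
256×256 frame at 0.5 mm/pixel, so the canonical 150 cycles/m fringe
spans ≈13 pixels — comfortably Nyquist-safe up to 500 cycles/m.  Its
components:

- **Reflectance and illumination field.**  Diffuse reflectance is a
  per-sample base level (U(0.75, 0.9)) darkened toward the rim by a
  radial cosine falloff whose depth is jittered per sample (0.3 ± 0.15),
  and multiplied by a per-sample linear illumination gradient (up to 15%
  across the fruit, random direction — projector/sample geometry).  Both
  are pure illumination effects: they cancel exactly in RT but
  contaminate DC and AC, which is what structurally separates RT-feature
  from AC-feature classification performance.  The falloff is partial
  (not to zero) so that a mid-level threshold still recovers the full
  ellipse support.
- **Modulation transfer.**  The AC amplitude carries a factor
  `exp(-f / 350 cycles/m)` (signal attenuation with frequency) times a
  smooth multiplicative texture field (Gaussian noise smoothed at σ=8 px,
  relative std 1.5%).  The texture models subsurface scattering
  heterogeneity; crucially it survives the RT ratio, providing the
  within-class variance floor against which bruise contrast is measured.
  Without such a floor the CI would be independent of bruise depth
  (both between- and within-class variance would scale with the same
  contrast factor) and the frequency sweep could not work.
- **Bruise.**  A disk (radius 24/29/34 px for S1/S2/S3 — the footprint of
  a ~3 cm probe on an ~8 cm fruit, growing mildly with load) with a
  smoothstep edge taper over the outer 20% of its radius.  Its AC
  attenuation depth follows the single-peak curve
  `c(f) = δ · (f/f_peak) · exp(1 − f/f_peak)` with `f_peak` = 150
  cycles/m: zero at f=0, rising to δ at the peak, decaying beyond — the
  simplest one-parameter rise-then-fall shape.  Default depths are
  δ = 0.25/0.45/0.65 for S1/S2/S3; the *weak-contrast* condition used for
  the AC-versus-RT comparison roughly halves them (0.12/0.22/0.33).
  S0 phantoms have an identically zero attenuation map.
- **Noise.**  Additive Gaussian sensor noise (default σ = 1 count)
  followed by clipping to [0, 255] and rounding (8-bit quantization).
  Both stages can be disabled for exactness tests.

What the phantoms do *not* model: radiative transfer or diffusion-theory
light propagation, RGB/color, specular reflection, fruit-to-fruit shape
variation beyond an ellipse, stem/calyx structures, and real bruise
morphology (which is neither circular nor radially symmetric).  Passing
tests therefore demonstrate that the *algorithms* behave as designed
under controlled contrast, noise and nuisance conditions — not that any
particular accuracy will transfer to real fruit.

## Demodulation

DC = (I₁+I₂+I₃)/3 and AC = (√2/3)·√((I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²),
computed in float64.  For ideal sinusoids with equally spaced offsets
these are exact at every pixel and every carrier phase (the three squared
pairwise differences of equally spaced cosines sum to 4.5·A²); common-mode
offsets cancel in the differences.  The AC image is denoised with a
Gaussian low-pass (default σ = 2 px, reflective boundaries, kernel
truncated at 6σ so the discrete kernel matches the analytic one to
<1e-6) before the ratio is formed.  When a fruit mask is available the
smoothing is a normalized convolution restricted to the mask — plain
smoothing drags the dark background into the fruit rim and creates a
spurious dark ring in RT that Otsu then mislabels as bruise.  RT division
is guarded: pixels with DC ≤ 1e-9 map to 0 (they are masked out
downstream anyway).

## Segmentation

The fruit mask comes from thresholding the DC image (default: 10% of the
dynamic range — one global value, since the imaging geometry is fixed),
followed by closing with a 3 px disk, hole filling, and retention of the
largest 4-connected component.  Within the mask, Otsu's threshold on RT
splits bruise (darker class) from sound tissue.  The Otsu score is
computed on a 256-bin histogram over the masked min–max range using
integer bin-index arithmetic, which keeps tie plateaus exactly equal and
makes the lowest-maximizing-threshold tie-break deterministic.  Otsu
always returns a split, even for sound fruit; a warning fires when the
between-class variance explains less than a configurable fraction
(default 10%) of the total.  Known limitation: for small, mild bruises
(a few percent of fruit area at low contrast) the threshold can land
inside the sound-tissue distribution — the familiar small-minority
failure mode of Otsu — which is visible in the phantom studies as
occasional poor S1 bruise masks.  This does not affect classification,
which uses whole-fruit texture, but it is why the frequency-selection
rule privileges mild-bruise contrast.

## Contrast index and frequency selection

CI = [N_x(x̄−z̄)² + N_y(ȳ−z̄)²] / Σ(zᵢ−z̄)², the ratio of between-class to
total variance of the fruit pixels (bruise x, sound y, union z); it lies
in [0, 1] and is invariant to affine intensity rescaling.  CI is computed
on RT (mild bruises are too faint to segment reliably in AC).  The sweep
renders three replicate phantoms per degree (matching a three-sample
frequency-selection design), re-images the same phantoms at each
frequency in {50, …, 500} cycles/m, and averages CI per cell.  Selection
follows a *mild-first* rule: choose the frequency maximizing CI for the
mildest degree, breaking ties by the next degree and then by the lower
frequency — mild bruises are the hardest to detect, so the operating
point is chosen for them.  Failed cells (segmentation errors) are
recorded as missing and exclude their frequency from selection.

## Texture features

Images are linearly quantized to 32 gray levels over the masked min–max
range (per-image normalization mirrors RT's illumination-corrected
contrast; 32 levels balances co-occurrence sparsity against
discrimination and is configurable).  One symmetric, normalized GLCM is
accumulated per direction (0°, 45°, 90°, 135°, distance 1), counting only
pixel pairs fully inside the mask, and the 14 classical Haralick
statistics are computed per direction — 56 features per image, in a fixed
documented order.  Conventions: logs are base 2 with 0·log 0 ≡ 0; sum
variance is taken about the sum average (the standard erratum fix);
correlation-type statistics and the information measures fall back to 0
when marginal variance or entropy vanishes; the maximal correlation
coefficient is √(second-largest eigenvalue of the Q matrix) restricted to
occupied levels, defined as 0 when fewer than two levels are present.
The 45°/135° direction convention follows the classical figure (45° pairs
up-right); scikit-image's diagonal angles are mirrored relative to it.

## Random-frog selection

The selector walks over feature subsets: from a subset of size Q it draws
a candidate size Q* ~ round(N(Q, max(1, θQ))) and mutates toward it.  The
proposal std is floored at one feature because θQ alone lets the walk
freeze once the subset shrinks to a couple of members.  Moves alternate
(50/50) between *guided* proposals — rank candidate features by |PLS
regression coefficient| and keep the best, as in the original
algorithm — and uniform random adds/removes; guided moves find
informative features quickly, uniform moves keep the walk from locking
onto whichever spurious features it met first.  A candidate is scored by
stratified k-fold (default 5) cross-validated PLS-DA error, with the
latent-variable count fixed per subset by the same cross-validation
(capped at min(10, subset size)).  Candidates within one cross-validated
sample of the current error are accepted outright — on an error plateau
this lets redundant features churn while features whose removal genuinely
costs accuracy persist — and worse candidates are accepted with
probability η·(err_current/err_candidate), η = 0.1.  A feature's
selection probability is its occupancy fraction over iterations.
Because the selected subset depends on the data split, the run is
repeated over 30 stratified 7:3 partitions; each run's top-10 earns one
count and the final subset is the ten features with the highest counts
(ties: higher mean probability, then fixed feature order).  Defaults
(1000 iterations, Q=10, θ=0.3, η=0.1) are in the range of the original
algorithm; the scaled studies here use 200 iterations, which the
planted-feature experiments show is sufficient at 56 features.

## Classifiers and evaluation

All three models are implemented in-package and standardized features
(z-score fit on the training fold) are used throughout:

- **LS-SVM** with RBF kernel exp(−‖u−v‖²/σ_k²): training solves the
  (n+1)×(n+1) KKT system [[0, 1ᵀ],[1, K+I/γ]]·[b; α] = [0; y] by dense
  LU; the residual is checked (<1e-8 expected) and a singular or
  ill-conditioned system raises with a suggestion to increase γ.
  (γ, σ_k) are tuned per training set by 10-fold cross-validation on a
  7×7 log grid (γ ∈ 10^[−1,4], σ_k ∈ 10^[−1,2]).
- **PLS-DA**: NIPALS PLS1 on 0/1 class coding thresholded at 0.5; the
  latent-variable count is chosen by leave-one-out cross-validation with
  ties to fewer components.  At full rank the fit equals ordinary least
  squares, which the tests verify.
- **KNN**: Euclidean majority vote, K odd (no vote ties), distance ties
  broken toward the smaller training index via a stable sort; K tuned by
  10-fold cross-validation over {1, 3, …, 15}.

Evaluation repeats a stratified 7:3 split 30 times per condition
(positives: bruised samples of the scoped degree(s); negatives: sound
S0), optionally restricted to a selected 10-feature subset, and reports
TP rate, TN rate and overall accuracy as means with standard errors over
repetitions.  Rows are canonically sorted by sample id before any seeded
split, so results are invariant to input ordering.  Feature-selection
partitions and evaluation splits use independent seeds.

## Problem sizes used by the shipped studies

The packaged acceptance study runs at 30 samples per class (S0–S3), 200
random-frog iterations over 30 partitions, and 30 evaluation
repetitions, with the weak-contrast bruise depths; the frequency sweep
uses 3 noiseless replicates per degree over the ten standard
frequencies.  These sizes were chosen so the whole study runs in a few
minutes on one CPU while leaving the qualitative structure of the
full-scale design (100 samples per class, deeper frog runs) intact.

## Reproducibility

Every stochastic component takes an explicit seed; per-sample and
per-stage seeds derive deterministically from one master seed (SHA-256 of
`"{seed}:{stage}"`).  Identical configurations reproduce bit-identical
images, feature tables and evaluation CSVs, which the pipeline tests
assert via checksums.
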