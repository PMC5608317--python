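# Methods

## Overview

`grassvlad` classifies RGB texture images — the motivating application is
H&E-stained breast-carcinoma histology, where Nottingham grade correlates
with spatially evolving tissue texture — by treating every small patch as a
linear dynamical system over pixel positions, summarizing each system as a
subspace on the Grassmann manifold, aggregating each image's subspace cloud
into a VLAD vector against a learned manifold codebook, and classifying the
vectors with an RBF-kernel SVM.

## The patch-level dynamical model

A patch is an N×N×3 tensor Y with values in [0, 1] (integer images are
divided by their dtype maximum).  Pixels are read in row-major scan order
and modeled as observations of a 3-state linear dynamical system

    x(i+1) = A x(i) + process noise
    I(i)   = Ī + C x(i) + observation noise,

with A ∈ R^{3×3} and an orthonormal mapping matrix C ∈ R^{3×3}.  The
orthonormality of C lets the model be identified through the higher-order
SVD: after subtracting the per-channel mean Ī, C is the mode-3 Tucker
factor U3 of the centered tensor, and the state sequence is the mode-3
unfolding of the core-reduced tensor, computed through the exact identity
X₍₃₎ = U3ᵀ Y₍₃₎.  Every SVD factor is sign-fixed (the largest-magnitude
entry of each singular vector is made positive) so identification is
bitwise deterministic.

Each patch is also rotated 90°, 180° and 270° clockwise and re-identified,
so the four scan directions (right, up, left, down) each contribute a
system; rotation permutes the mode-3 unfolding columns, so all four share
the same C while A differs.  Patches whose centered Frobenius norm falls
below eps·N (default eps = 1e-8) have no identifiable dynamics and are
excluded (counted and logged).

### Transition estimation

A is the one-step least-squares regression of consecutive states.  Two
numerical choices matter here:

* **State centering.**  Subtracting the *empirical* observation mean leaves
  an affine offset (A − I)·x̄ in the state recursion, which biases the
  homogeneous regression.  Both state matrices are therefore column-centered
  before the regression; because the mean of x(2..n) equals A·mean(x(1..n−1))
  plus that offset, centering removes it exactly, and a noiseless patch from
  a stable system is recovered to machine precision.
* **No absolute ridge.**  The default solve is the minimum-norm least squares
  A = X_next · pinv(X_prev) with a relative singular-value cutoff (1e-12).
  An absolute ridge (an available option) biases weakly excited trajectories:
  decayed state sequences have Gram eigenvalues of order 1e-6, where a 1e-8
  ridge already moves the recovered subspace by ~1e-3.

### Stabilization

The descriptor assumes |λ₁(A)| ≤ 1; σ₁(A) ≤ 1 is the certificate used (it
bounds the spectral radius).  When the least-squares fit has σ₁ > 1 + tol
(tol = 1e-6), the objective ‖X_next − A X_prev‖²_F is re-minimized by
constraint generation: at each iterate the top singular pair (u₁, v₁)
contributes a linear constraint ⟨u₁v₁ᵀ, A⟩ ≤ 1, and the quadratic program
with P = I₃ ⊗ (X_prev X_prevᵀ), q = vec(X_next X_prevᵀ) is re-solved until
σ₁ ≤ 1 + tol.  A single constraint bounds σ₁ only along one direction pair,
so iteration (default cap 50 rounds) is required for the certificate.  The
QP (9 variables, a handful of constraints) is solved by an exact primal
active-set method with direct KKT solves, warm-started at the spectral
rescaling A/σ₁(A) — which satisfies every constraint, so the result is never
worse in objective than naive rescaling; scipy's SLSQP is the fallback if
the active set cycles.  Only unstable fits are touched: a stable A is
already feasible and optimal.

## Grassmannian representation

Each system maps to the column span of its observability matrix
O = [C; CA; …; CA^{m−1}] (horizon m = 3 by default, giving 9×3), a point on
Gr(9, 3); the span is invariant to the state-basis ambiguity of the
identification.  Orthonormalization uses QR with the R diagonal forced
positive (deterministic Gram–Schmidt); rank deficiency below 1e-10 relative
raises an error (the system is unobservable at that horizon).

The metric is the arc-length geodesic distance d = √(Σ θᵢ²) over principal
angles θᵢ, realized as the Frobenius norm of the inverse exponential map.
log and exp use the standard thin-SVD constructions (tangent = U arctan(Σ) Vᵀ
of (I − XXᵀ)Y(XᵀY)⁻¹, and its cos/sin inverse).  Pairs with a principal
angle of π/2 (XᵀY singular below cos θ = 1e-10) are on the cut locus and
raise a flagged error instead of silently choosing a branch.  Batched
helpers compute the same metric through arccos of singular values of XᵀY;
the two routes agree to ~1e-14 and are cross-checked in the tests.

Karcher means iterate μ ← exp(μ, mean log(μ, pᵢ)) with unit step until the
mean-tangent norm falls below tol = 1e-6 (guaranteed to converge for data
inside an injectivity-radius ball, which codebook clusters satisfy in
practice); k-medoids runs on a precomputed distance matrix with a seeded
farthest-point initialization and lowest-index tie-breaking.

## Codebook and VLAD encoding

The vocabulary is learned from training images only: points are pooled,
uniformly subsampled (seeded) to at most `subsample_cap` (default 2,000 —
the medoid initialization needs the full O(n²) distance matrix, which is the
binding cost), initialized by k-medoids, averaged per cluster by Karcher
means, and refined by up to 10 reassign/re-average rounds with early
stopping; an emptied cluster is re-seeded to the point farthest from its
nearest word.  Default k = 16.

Two encodings are provided.  The default, `scalar_as_printed`, aggregates
per word the *norms* of the log maps from the word to its assigned points
(equivalently their geodesic distances), yielding a k-vector — the method's
literal aggregation rule.  `tangent_vlad` aggregates the log-map matrices
themselves and concatenates the k blocks (length k·9·3), the form classical
VLAD suggests.  Which of the two the original formulation intended is
genuinely ambiguous, so both are first-class and selectable; assignments are
identical under either.  Codes are L2-normalized; residuals below 1e-7 (the
arccos noise floor near identical subspaces) are treated as exact zeros, and
an all-zero raw vector is returned unnormalized with a `is_zero` flag.
Summation runs in ascending point order for bitwise determinism.

## Classification and protocols

An SVC with RBF kernel is trained per fold; C ∈ {1, 10, 100} and kernel
widths {0.01, 0.1, 1, 10}·δ (δ = median pairwise training-code distance,
gamma = 1/(2 width²)) are selected by an inner seeded 3-fold stratified grid
search on the training set only; multiclass is one-vs-one.  Protocols:
stratified image-level k-fold CV (default 5 folds), and patient-wise
holdout in which *patients* are split ~70/30 per class over 5 seeded trials
and images follow their patient — a hard assertion forbids any patient
straddling a split.  Metrics: image classification rate N_c/N_all; patient
score (fraction of a patient's images correct); global patient rate (mean
of patient scores).  The codebook is learned inside each training fold by
default; a shared-codebook mode (vocabulary sees all images) exists behind
a flag and is recorded in the report.

## Synthetic data

The generator emulates the study datasets with known class-conditional
dynamics.  Per class, a system is drawn (A = rotation-like matrix scaled to
σ₁ = 0.97·U(0.7, 1); C Haar orthogonal; channel means in [0.4, 0.6]) and
classes are rejection-sampled until all pairwise observability-subspace
distances reach `class_separation` (default 0.8; the achieved value is
recorded).  Images (default 128×128) are mosaics of 8×8 tiles, each an
independent realization (fresh initial state) of the class system, so tiles
are i.i.d. draws of the structure the per-patch pipeline assumes.  Defaults
chosen once: process noise σ_v = 0.25 (state units; keeps textures excited
rather than decaying to flat), observation noise σ_w = 0.01 (~2.5 gray
levels), and an observation amplitude obs_scale = 0.05 multiplying C·x —
without it, unit-variance states would saturate the [0, 1] range and the
clipping would destroy the linearity the recovery tests rely on; at 0.05
with means ≥ 0.4 clipping needs an ~8σ excursion.  Ground truth goes to a
sidecar JSON that the pipeline never reads; 21 patients (7 per class of 3)
mirror a realistic patient count.

What the generator does *not* emulate: nuclei/stroma morphology, stain
variation, illumination gradients, spatial nonstationarity within an image,
or label noise.  Passing the synthetic benchmark therefore shows the
pipeline recovers and separates *known* class dynamics end to end; it does
not by itself establish accuracy on real histology.

## Problem sizes and runtime

The default benchmark — 3 classes × 30 images at 128×128, 8×8 overlapping
patches (50% overlap: 961 patches × 4 directions = 3,844 points per image),
m = 3, per-fold codebooks, 5-fold CV — runs in a few minutes on one CPU:
identification is fully vectorized over patches (batched LAPACK SVD/QR),
point clouds are cached on disk keyed by a hash of the identification
config, and codebook training caps its subsample at 2,000 points.  The
acceptance script reuses the same cache across its k ∈ {8, 16, 32} sweeps.

## Known limitations

* The scalar VLAD code is only k-dimensional; with few classes and strong
  separation this is ample, but on subtle real-world textures the tangent
  variant (432-dimensional at k = 16) may be the better default.
* Stabilization certifies σ₁ ≤ 1 + tol, a sufficient but conservative
  stability condition (matrices with σ₁ slightly above 1 but spectral radius
  below 1 are also modified).
* Patches straddling tile boundaries of the synthetic mosaics mix two
  realizations of the class system; their fits are attenuated but remain
  class-informative, and they are deliberately kept (the real pipeline has
  no tile oracle).
* The log map is undefined at principal angle π/2; such pairs abort the
  operation with a flagged error rather than being projected around the cut
  locus.  They do not arise in practice for fitted descriptor clouds.
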