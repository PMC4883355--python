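# Methods

## Problem and data model

The classifier's input is the vertical (y-axis) coordinate of a mounted
rider's hip, captured at 100 frames/s and cut into 100-sample windows
(1 s each). Each window is one sample; a dataset is a dimensions ×
samples matrix with one gait label per column. The canonical study
geometry is 100 × 160: 40 windows for each of walk, sitting trot, rising
trot and canter, split 20/20 per gait into training and test halves.
Labels are coded walk = 1, sitting trot = 2, rising trot = 3,
canter = 4 and treated as a single scalar regression target; a one-hot
multi-output formulation was deliberately not used, keeping the
consequent solve a single least-squares problem and prediction a
nearest-code decode (ties to the lower code, outputs clipped to the code
range by the decode itself).

Motion tables are flat delimited text: one row per frame, 84 columns (28
body sites × x, y, z in a fixed site-major order, documented in the file
header). Units are carried opaquely; nothing downstream assumes a scale.
Full capture-format parsing (skeleton hierarchies, rotation channels) is
out of scope — only the positional table matters here.

## Wavelet-packet features

Features are wavelet-packet coefficients: both the approximation and the
detail branch are split at every level, giving 2^j subbands ("nodes") at
layer j, indexed [j, k] in natural filter-bank order. The plain wavelet
transform is recovered as the [j, 0] path.

Numerical choices:

* **Wavelet: Haar (db1).** Its filter length 2 makes the coefficient
  length cascade exactly floor((n + L − 1)/2): 100 → 50 → 25 → 13.
  Longer filters would pad these lengths and break the 25-row feature
  block geometry.
* **Boundary handling: half-point symmetric extension**, the
  conventional default with those lengths. For Haar at even lengths
  there is no boundary overlap, so per-layer energy is conserved
  exactly at layers 1–2 of a 100-sample window; the odd-length 25 → 13
  split duplicates one boundary sample and is not exactly orthogonal,
  which is why energy checks are stated per layer rather than at depth
  3.
* **Default feature block: node [2, 0] alone** (the layer-2
  approximation), since its 25 rows match the reduced data geometry; a
  `node="all"` mode concatenates a whole layer when broader spectral
  content is wanted.

Decomposition and reconstruction are delegated to PyWavelets; this
package contributes the node bookkeeping, dataset-level feature
assembly, and provenance-carrying text I/O.

## Fuzzy c-means (FCM)

FCM minimises J_m = Σ_i Σ_j u_ij^m ‖x_i − c_j‖² over memberships
u_ij ∈ [0, 1] (summing to 1 per point) and centers c_j, by alternating
the closed-form updates

* c_j = Σ_i u_ij^m x_i / Σ_i u_ij^m,
* u_ij = 1 / Σ_k (d_ij / d_ik)^(2/(m−1)),

from a seeded random membership matrix, stopping when
max_ij |u_ij^(k+1) − u_ij^(k)| < ε. Defaults: fuzzifier m = 2 (the
universal choice; m → 1⁺ approaches hard k-means), ε = 1e−5, 200
iterations max. The membership update runs in the log domain so small
fuzzifiers (exponent 2/(m−1) large) cannot overflow before
normalisation. A point exactly coincident with a center receives full
membership in (the first of) the coincident center(s) — the standard
limit of the update, which otherwise divides by zero. J_m is
non-increasing across iterations by construction and this is asserted in
tests on every fit.

## The TSK neuro-fuzzy classifier

Each FCM cluster becomes one rule: premise centers are the cluster
center, premise widths the u²-weighted standard deviation of each
dimension around it (the same u^m weighting as the center update, so a
cluster's width reflects the points it owns). Widths are floored at
1e−3 of the dimension's data range (1e−3 absolute if the range is zero)
so degenerate clusters keep positive spread. Widths are per-rule and
per-dimension; a single shared width would collapse the rule geometry
that scatter partitioning exists to provide.

Inference: firing strengths are products of per-dimension Gaussians
(product t-norm, the standard TSK choice), computed in the log domain
and normalised with a max-shift so that high-dimensional products
cannot underflow; if every strength still vanishes numerically the
weights fall back to uniform with a logged warning. The output is the
convex combination Σ w̄_i f_i(x), so it always lies between the smallest
and largest consequent value — a useful sanity bound asserted in tests.

Hybrid learning, per epoch:

1. **LSE for consequents.** With premises frozen the output is linear in
   the stacked consequents; the design row for sample x is
   [w̄_1·(x,1), …, w̄_r·(x,1)]. The solve is ridge-regularised
   (default 1e−8) or minimum-norm when the ridge is zero. With r rules
   on d-dimensional data there are r(d+1) unknowns, typically far more
   than training samples (33 × 26 = 858 versus 80), so the system is
   solved in its dual (kernel) form — an N × N solve — which is exact
   and orders of magnitude faster than factoring the full design.
   Consequents may also be restricted to constants (zero-order TSK) by
   configuration.
2. **Backprop for premises.** One full-batch gradient step on
   Σ(f(x) − y)² with respect to every center and width, with analytic
   gradients propagated through the normalised weighted average
   (verified against central finite differences in tests). Widths are
   re-floored after the step. The learning rate (default 0.01) halves
   whenever a step would raise the training SSE; after ten halvings the
   premises stay frozen for that epoch. This simple control keeps the
   SSE monotone without a line search.

A final LSE pass re-optimises the consequents for the adapted premises.
The whole pipeline is deterministic for fixed seeds: FCM initialisation
is the only randomness.

The rule count is user-set; the practical range for these data is
2–50, and the `rule_sweep` helper scans a range against a validation
split. The package default of 33 matches the study-scale configuration
used by the acceptance runs.

## Synthetic gait generator

The generator emulates the qualitative hip-rhythm signatures, not horse
biomechanics: each gait is baseline + A(t)·sin(θ + k·sin θ) with
θ = 2πft, where A(t) attenuates every second cycle (posting) and k skews
the waveform (three-beat roll). Committed defaults, in metre-scale hip
units per 1-s window:

| gait | f (cycles/window) | amplitude | alternation | asymmetry |
|---|---|---|---|---|
| walk | 2 | 0.012 | – | – |
| sitting trot | 4 | 0.05 | – | – |
| rising trot | 4 | 0.06 | 0.5 | – |
| canter | 3 | 0.07 | – | 0.6 |

All gaits share baseline 1.0, i.i.d. Gaussian noise sd 0.01 and a
per-window Gaussian phase offset sd 0.15 rad standing in for imperfect
stride synchronisation. The noise floor equals the walk amplitude, so
the easiest class is genuinely noisy, while the trots and canter differ
in rhythm rather than in trivially separable statistics. What passing
tests show is that the pipeline recovers controllable class structure
under noise and phase jitter; they do not certify performance on real
rider data, whose within-gait variability (horse, speed, rider posture,
sensor drift) the generator does not model.

## Evaluation harness

Splits are stratified by default (the balanced 20-per-gait geometry),
with plain random splitting by flag; stratified k-fold is provided as
well since both a 50/50 holdout and 10-fold cross-validation are common
protocols for this task. Accuracy is 100 × trace/total of the confusion
matrix and the two are asserted consistent. The harness accepts any
classifier with a `fit(train_dataset)` / `predict(signals)` contract, so
baselines (a nearest-template classifier ships in the package;
scikit-learn estimators need a three-line adapter) can be compared with
the FCM-NFC without special casing.

## Problem sizes and known limitations

Test and acceptance runs use the 100 × 160 study geometry (and smaller
fixtures for unit tests); each end-to-end fit takes under two seconds on
one CPU. Known limitations: the premise gradient materialises an
N × rules × dimensions array, fine at these scales but memory-hungry for
very large datasets; the LSE interpolates when rules × (dims + 1)
exceeds the sample count, so generalisation rests entirely on the
locality of the Gaussian premises; and the class-code regression imposes
an ordinal structure on what is really a nominal label set — adjacent
codes are more easily confused by construction.
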