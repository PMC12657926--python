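# Methods

## Overview

`braingraph` turns grayscale images (its motivating inputs are T1-weighted
MRI slices of dementia patients) into pixel-similarity graphs, summarizes
each graph with six distance-based topological indices, places the indices
on a common scale with a matched Watts–Strogatz (WS) ensemble, and
classifies four ordered disease stages from the resulting six-feature
vectors. This note records the models, parameter choices, numerical
decisions and known limitations.

## Pixel graphs from images

For an image with `mn` pixels (row-major, 0-based), the Brightness
Distance Matrix is `L(p, q) = |Lum(p) − Lum(q)|`, min-max normalized to
`L_n ∈ [0, 1]`, and thresholded: pixels `p ≠ q` are adjacent iff
`1 − L_n(p, q) ≥ τ`. Self-loops are excluded, and edge count is
non-increasing in τ.

Two structural facts about this construction shape everything downstream:

* **Affine invariance.** `L_n` is unchanged by any affine intensity map
  `x → a·x + b` (a > 0), so the graph depends only on the *shape* of the
  intensity histogram, never on brightness or contrast per se.
* **Interval-graph structure.** Adjacency depends only on the difference
  of scalar intensities, so the pixel graph is the interval graph of the
  pixel-intensity multiset: spatial arrangement is irrelevant. Dense
  histogram regions become clique-like blocks; sparse tails become long
  chains; gaps wider than `(1 − τ)·range` split components. One practical
  corollary: the mean local clustering coefficient of these graphs is
  structurally pinned near 0.75–0.8 for any unimodal-ish histogram, so
  clustering is a poor between-class discriminator, while path-based
  quantities (average path length, Wiener index) respond strongly to
  histogram tails.

Defaults: τ = 0.95 (keeps graphs sparse enough for exact index
computation while staying connected for realistic histograms); working
resolution 32×32 by area-averaged (box-filter) downsampling, because the
dense `mn × mn` BDM at native MRI resolution (176×208 → 36,608 pixels)
would need ~1.3·10⁹ entries. Both are configurable, including native
resolution. Distance-based indices are undefined across components, so the
pipeline restricts to the largest connected component (ties broken toward
the component containing the smallest pixel index) and records the
component size.

Degenerate case: a constant image has `max L = min L`; its normalized BDM
is defined as all zeros (logged as a warning), which makes the τ-graph
complete for every τ — the natural limit of "all pixels equally similar".

## Distance-based indices

For edge `e = rs`, `alpha_r` (resp. `alpha_s`) counts vertices strictly
closer in hop distance to `r` (to `s`); equidistant vertices count toward
neither. The indices are

* Szeged `Sz = Σ_e α_r·α_s`
* Graovac–Ghorbani `ABC = Σ_e sqrt((α_r + α_s − 2)/(α_r·α_s))`
* Padmakar–Ivan `PI = Σ_e (α_r + α_s)`
* Mostar `MO = Σ_e |α_r − α_s|` (zero iff the graph is distance-balanced)
* normalized Graovac–Ghorbani `NGG = Σ_e 1/sqrt(α_r·α_s)`
* Wiener `W = Σ_{unordered pairs} ρ(r, s)`.

The Wiener sum is taken over unordered distinct pairs; the ordered-pair
reading would be exactly 2W and would only rescale the feature. All six
indices are computed from one BFS all-pairs distance matrix
(`scipy.sparse.csgraph`) and one vectorized partition pass (distances cast
to int16; edge blocks of 4096 keep buffers small). The test suite checks
every index against a deliberately naive oracle that re-runs BFS per edge.

## Watts–Strogatz model

A ring lattice on `v` vertices ties vertex `i` to `i ± 1 … i ± δ/2`
(δ even). Rewiring proceeds sequentially — span u = 1 first, then u = 2,
… — and each lattice edge `(i, i+u)` is independently rewired with
probability p: the far endpoint is replaced by a uniform random vertex
that is neither `i` nor already adjacent to `i` (edge count conserved; if
`i` is adjacent to all others the edge is kept and the event logged).

On the unrewired lattice the strictly-closer counts of a span-u edge admit
the closed form `α_u = u(C−1) + γ` if `γ < u`, else `uC + 1`, with
`C = ⌊(v−1)/δ⌋`, `γ = (v−1) mod δ`. The package exposes both this closed
form verbatim and a BFS oracle, plus an audit that tabulates agreement per
branch. The `γ ≥ u` branch agrees everywhere we have scanned
(v ≤ 60, even δ < v/2). The `γ < u` branch does not always match the BFS
count — the smallest counterexample is (v=10, δ=4, u=2): closed form 3,
BFS 4 — so the audit reports rather than asserts that branch, and the BFS
oracle is treated as ground truth throughout the tests.

Ensemble scans average the six indices (computed on the largest component
if rewiring disconnects a replicate) plus clustering and average path
length over seeded replicates per grid probability; extremum locations are
reported with ties broken toward smaller p. At v=50, δ=10 with grid step
0.05 and 200 replicates per point, the ensemble-mean Mostar curve in our
scans rises from 0 at p=0 to its global maximum at the first nonzero grid
point (p = 0.05) and then decays toward a plateau — a slightly perturbed
lattice is maximally distance-unbalanced — while the mean ABC and NGG
curves attain interior minima near p ≈ 0.3. These locations are invariant
under any per-index monotone rescaling of the curves. This behaviour is
recomputed, not assumed, by `scripts/acceptance.py` and the scan test.

## WS normalization of features

Each image's raw index vector is divided componentwise by the mean index
vector of a matched WS ensemble: v equal to the pixel graph's component
size, δ the nearest even integer ≥ 2 to its mean degree, reference
probability p_ref = 0.25 (the center of the small-world sensitivity
range), and a configurable replicate count (default 100). The Mostar
component is divided by `mean + 1` because a distance-balanced reference
(any lattice at p = 0) has mean MO = 0. This ratio-to-matched-null
normalization is the analogue of the C/C_rand-style scaling used in
small-world analysis. References are cached per (v, δ) within a run.

## Synthetic images

Because of affine invariance and the interval-graph property, class
structure in synthetic images must be carried by histogram shape. Each
image is generated as:

* a parenchyma field: white noise convolved with a Gaussian kernel of
  length `smooth_len`, normalized by the kernel's theoretical white-noise
  gain (so heavy smoothing degenerates to a near-constant field instead of
  being re-amplified), scaled to sd `0.22·contrast` around mid-gray 127.5;
* "atrophy" regions: the top `lesion_frac` quantile of a second correlated
  field, displaced to a broad dark band centered `1.2·contrast` below
  mid-gray with sd `0.65·contrast`;
* additive white noise (`noise_sd`), clipped to [0, 255].

Stage recipes: `smooth_len` = 6.0 / 4.0 / 2.6 / 1.6 and `lesion_frac` =
0.03 / 0.09 / 0.18 / 0.30 for stages 0–3, with contrast 55 and noise sd 3
gray levels throughout. The growing displaced fraction thickens the
histogram's dark tail, so pixel graphs acquire longer sparse chains: mean
average path length and Wiener index increase strictly with the stage
label (the separable covariate the classifier uses), while clustering
stays pinned as explained above. All randomness flows from one root seed
through `numpy.random.SeedSequence.spawn`, one stream per image, so
datasets are reproducible and order-insensitive.

What the generator does *not* emulate: anatomy, bias fields, partial
volume, scanner noise statistics, or any spatial disease signature —
passing classification tests on these fixtures demonstrates that the
pipeline detects histogram-level class structure end to end, not that it
stages real MRI.

## Classification

Features are the six (normalized) indices; labels are the four ordered
stages. SMOTE oversampling (synthetic points `x + λ(x_nn − x)`, λ ~ U(0,1),
x_nn one of the k = 5 nearest same-class neighbors) balances every class
to the majority count; it is applied inside each cross-validation training
fold only — never to validation or test data. Splits are stratified and
seeded (80-20 holdout; 5-fold CV).

Model families: CART decision tree; multinomial logistic regression;
SVM with the RBF kernel `exp(−‖x−x′‖²/(2σ²))` at σ = 1 (kernel coefficient
0.5); and two multilayer perceptrons, `nn2` with hidden layers (64, 32)
and `nn4` with hidden layers (128, 64, 32, 16), softmax outputs, Adam
(step 1e−3), batch size 32, 150 epochs, minimizing categorical
cross-entropy. The MLPs are trained by an explicit minibatch loop so the
validation cross-entropy can be recorded per epoch; an L2 penalty
(α = 1e−3) is the overfitting control. Scale-sensitive families
(logistic, SVM, MLPs) standardize features using training-partition
statistics only; trees are scale-invariant and skip this. Zero predicted
probabilities in the cross-entropy are clipped at 1e−12 and logged.

Metrics: accuracy; support-weighted precision/recall/F1; one-vs-rest
macro-averaged AUC over the classes present in the truth (absent classes
are excluded and logged); per-fold 4×4 confusion matrices; per-epoch loss
curves for the MLPs.

## Problem sizes used by the test suite

Exact index computations are validated on 50 random connected graphs
(5–30 vertices) and 50 random trees (5–40 vertices). The ensemble scan
runs v=50, δ=10, 21 grid points × 200 replicates. The staging property
uses 50 images per class at 32×32 with a 1-replicate normalization
reference (the reference mean enters every feature of a (v, δ) group
identically, so the replicate count affects variance of the scale, not the
class signal); the end-to-end determinism check uses 6 images per class at
16×16. These sizes keep the whole suite within a few minutes on one core
while exercising every stage at full fidelity.

## Known limitations

* Index computation is exact and dense (O(V·E) time, O(V²) memory); pixel
  graphs beyond ~10⁴ vertices need downsampling first.
* The pixel graph ignores spatial structure by construction; two images
  with identical histograms produce isomorphic graphs.
* WS normalization replicates default to 100 but even 1–2 replicates give
  a usable scale; the reference is a Monte-Carlo estimate either way.
* `SVC(probability=True)` relies on internal Platt scaling; its
  probabilities are smoothed, though predictions are deterministic per
  seed.
* The closed-form lattice count is reported verbatim on its `γ < u`
  branch even where BFS disagrees; consumers should rely on the audit (or
  the oracle) for ground truth.
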