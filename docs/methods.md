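# Methods

## The model

`fgdn` classifies subjects from resting-state functional-connectivity
matrices. The design addresses a specific weakness of flat classifiers on
connectivity data: the matrix entries are treated as unstructured features,
although they live on a graph of brain regions. The model instead anchors
each subject's features to two *class graph templates* and lets a spectral
graph network decide which template the subject's connectivity pattern fits.

### Connectivity features

Given a subject's ROI time-series matrix (T timepoints x N regions):

- **Covariance**: the Ledoit-Wolf shrunk estimator
  `(1 - a) S + a (tr S / N) I`, where `S` is the sample covariance of the
  de-meaned signal and the shrinkage intensity `a` in [0, 1] is set by the
  Ledoit-Wolf formula. Shrinkage guarantees a positive-definite estimate
  even when T is small relative to N. Time series are de-meaned but not
  variance-scaled before estimation (a config switch can change this; the
  choice matters little for the tangent features, which whiten anyway).
- **Tangent embedding**: covariances are SPD matrices and live on a curved
  manifold; the embedding maps them to a common tangent space where
  Euclidean operations are justified. The reference point G is the
  affine-invariant (Karcher) geometric mean of the *training* covariances,
  computed by the standard fixed-point iteration
  `G <- G^{1/2} exp( mean_i log(G^{-1/2} C_i G^{-1/2}) ) G^{1/2}`,
  initialized at the Euclidean mean and stopped when the Frobenius norm of
  the exponent drops below 1e-6 (at most 50 iterations; an arithmetic-mean
  reference is available as `tangent_mean="euclidean"`). A subject's
  feature matrix is then `logm(G^{-1/2} C G^{-1/2})`. The reference is
  fitted on training subjects only and reused for validation/test subjects
  — anything else leaks test statistics into the feature map.
- **Correlation**: the plain Pearson matrix, kept as the simpler baseline
  feature (`feature_kind="correlation"`).

### Class graph templates

For each class c, the element-wise mean of the training subjects'
connectivity matrices defines N node vectors (its rows). A KNN graph is
built on these rows: each node keeps its k nearest other nodes by Euclidean
distance (ties at the k-th distance broken by ascending node index), the
Gaussian-kernel width `theta` is the mean of all retained directed
distances, kept edges get weight `exp(-d^2 / (2 theta^2))`, and the
directed graph is symmetrized by element-wise max (union KNN). Union
symmetrization guarantees every node keeps at least k neighbors and the
weight matrix stays symmetric for the Laplacian; the node-local threshold
(k-th-neighbor distance) plus a single global kernel width makes the
construction scale-adaptive with one parameter. Self-loops are excluded.
The default k is 20; for small synthetic atlases the pipeline clamps k to
N - 1 (the template builder itself rejects k >= N).

A subject is then represented as two graphs that share its node features
(the rows of its own connectivity matrix) but carry the two class
templates' edges.

### The network

Spectral graph convolution filters a signal by a polynomial of the graph
Laplacian. With `L = I - D^{-1/2} W D^{-1/2}` (isolated nodes get a unit
diagonal), the largest eigenvalue computed exactly (N <= 128 makes the
`lambda_max ~ 2` shortcut pointless), and `Lt = 2 L / lambda_max - I`, a
K-order Chebyshev filter is `sum_k theta_k T_k(Lt)` with
`T_0 = I, T_1 = Lt, T_k = 2 Lt T_{k-1} - T_{k-2}`. The recursion is applied
directly to the feature matrix; the backward pass pushes gradients through
the same structure with a generalized Clenshaw recurrence (`T_k(Lt)` is
symmetric, so the adjoint is again a Chebyshev sum). K bounds the hop
radius a filter can see, which the tests verify on a path graph.

The network is: ChebConv(K=3, 64 channels) -> PReLU -> dropout ->
ChebConv(K=3, 64) -> PReLU -> dropout -> flatten -> dense(128) -> PReLU ->
dense(2) -> sigmoid. One set of weights serves both graphs: the subject's
ASD score is output unit 0 of the pass that used the ASD template, the HC
score is unit 1 of the HC-template pass (when the two templates coincide
the two passes collapse into one, so this reading is compatible with both
single-pass and dual-pass interpretations of the decision rule). The
subject is labeled ASD iff its ASD score strictly exceeds its HC score;
ties go to HC. Training minimizes the summed two-unit binary cross-entropy
(targets (1,0) for ASD, (0,1) for HC; probabilities clipped at 1e-7).

The model is implemented in NumPy with analytically derived gradients and a
self-contained Adam optimizer (classic L2 weight decay added to gradients;
biases and PReLU slopes exempt). The backward pass is validated against
central finite differences at 1e-5 relative tolerance.

Choices the architecture description leaves open, fixed here as defaults:
dense hidden width 128; Glorot-uniform initialization with K * d_in fan-in
for the Chebyshev tensors; PReLU slopes initialized at 0.25, one scalar
slope per layer; dropout applied to each graph-convolution activation.

### Training protocol

Adam with learning rate 1e-4, weight decay 5e-4, mini-batches of 16,
dropout 0.1. Ten percent of the training subjects (stratified by class) are
held out as a monitoring set used only for early stopping: training stops
once the monitoring accuracy has not improved for 20 epochs (cap 300) and
the best-monitor parameters are restored. The tangent reference and the
class templates are fitted on the non-monitor portion. Whether the
monitoring split should be stratified is an open protocol detail;
stratification stabilizes the small monitor sets used here.

## Evaluation harness

- **Metrics**: accuracy, sensitivity, specificity from the confusion
  matrix (ASD positive); AUC as the Mann-Whitney rank statistic of the
  score `p_asd - p_hc` (ties count half), undefined for one-class truth.
- **Cross-validation**: stratified k-fold (k = 5 or 10), shuffled under the
  config seed. Every stage — covariances, tangent reference, templates,
  network — is refitted inside each fold on training subjects only, and the
  evaluation step asserts that the id sets of training and test subjects
  are disjoint.
- **Leave-one-site-out**: one fold per acquisition site; probes robustness
  to site-level distribution shift.
- **Learning curve**: each fold's training set is subsampled (stratified,
  seeded) at the requested fractions while the held-out fold is unchanged;
  fraction 1.0 reproduces the plain cross-validation run bit-for-bit under
  the same seed.
- **Region discriminability**: per region, all *other* regions' node-feature
  rows are zeroed (template edges untouched), each trained fold model is
  fine-tuned on the masked training set (30 epochs at one-tenth learning
  rate — the published procedure says only "fine-tuned", so the budget is a
  package default), and the masked validation accuracy is the region's
  discriminative weight. Regions are ranked by mean accuracy;
  `pct_exceeded` counts, per region, the share of other regions it beats
  under a paired two-sided t-test across folds at p < 0.05, with no
  multiplicity correction (matching the per-pair "significantly higher"
  reading). Masking only the rows keeps the studied region's full
  connectivity profile; zeroing the reciprocal columns as well is available
  via `mask_columns=True`.

All randomness flows from the single config seed; identical seeds give
bit-identical histories, parameters and reports.

## Synthetic cohorts

Real multi-site clinical cohorts cannot ship with the package, so the test
bed is a generator whose cohorts exercise every pipeline stage. Subjects
are zero-mean stationary Gaussian time series (optionally AR(1)-smoothed;
off by default — temporal autocorrelation changes effective sample size but
not what the estimators compute). The two classes share a base covariance
drawn from a random sparse partial-correlation structure (random sparse
precision matrix, diagonal-loaded, inverted, normalized to unit diagonal);
the ASD class adds +/- `effect_size` to the covariance entries among the
designated signal regions, with alternating signs to keep the perturbed
matrix near SPD before eigenvalue clipping at 1e-6. Per-subject
heterogeneity is a random symmetric covariance perturbation
(`subject_noise`); sites scale a subject's covariance multiplicatively
(`site_shift`), because connectivity features are second-moment statistics
— a scanner gain shows up as a variance scale, not a mean offset. Subjects
alternate sites round-robin within each class, so every site contains both
classes (required by leave-one-site-out).

Default study conditions: 16 ROIs, 100 subjects per class, T = 150,
3 sites, effect 0.4 on signal regions (2, 5, 9, 12), site shift 0.1,
subject noise 0.05. With these settings an ideal observer of the true
covariances separates the classes nearly perfectly, so end-to-end recovery
tests are demanding of the pipeline rather than vacuous.

What the generator deliberately omits: hemodynamic response, motion and
scanner artifacts, global-signal confounds, heterogeneous ROI counts, and
site effects beyond variance scaling. Passing tests therefore demonstrate
that the pipeline recovers planted second-order structure under multi-site
variance shifts — not that any particular clinical accuracy is attainable
on real data.

A fixed 4-ROI, 8-subject worked example (class means with pairwise row
distances sqrt(2), sqrt(5), sqrt(8)) makes the template construction
hand-checkable; its k=2 template is frozen in the tests from a closed-form
hand computation.

## Problem sizes and numerical choices

The shipped experiments use the default cohort above: 5-fold
cross-validation, the permuted-label null, leave-one-site-out, the
learning-curve endpoints 0.2 vs 1.0 (5 folds), and region discriminability
on 50-subject-per-class cohorts with signal confined to 2 of 16 regions
(5 folds, 3 seeds). Tie-breaks are deterministic everywhere (stable sorts,
ascending-index neighbor ties); degenerate inputs are either defined
exactly (empty graph -> L = I; coincident nodes -> edge weight 1) or
rejected with the offending subject/ROI named. Reported metric summaries
are mean and sample SD (ddof = 1) across folds.

## Known limitations

- The summed (not averaged) batch loss ties the effective gradient scale to
  the batch size; the published learning rate assumes batches of 16.
- The geometric-mean fixed point is not guaranteed to converge for wildly
  dispersed covariances; it raises after 50 iterations rather than
  returning a poor reference.
- Region discriminability fine-tunes from fold models trained on full
  features; a region whose signal the full model ignored can score at
  chance even if informative in isolation.
- With a single scalar PReLU slope per layer, the activation is less
  expressive than per-channel slopes; this follows the minimal reading of
  the architecture.
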