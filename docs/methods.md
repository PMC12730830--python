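# Methods

## The synolitic representation

`synolitic` turns a tabular omics cohort — a samples × analytes matrix of
positive concentrations with a binary case/control label per sample — into
one weighted graph per sample and classifies those graphs.

**Edges.** For every unordered analyte pair (i, j), a linear soft-margin SVM
is fitted on just those two z-scored features to separate cases from
controls in the training partition (`C = 1.0` by default; the constant is
recorded in the experiment configuration). The SVM decision value is mapped
to [0, 1] by Platt sigmoid calibration fitted on the training decision
values (robust Newton variant with Platt's smoothed targets). The calibrated
score of pair model (i, j), evaluated on one sample's two concentrations, is
that sample's edge weight w_ij. A weight near 0.5 means the pair is
uninformative for this sample; deviations toward 0 or 1 encode the pair's
joint (synergistic or antagonistic) discriminative content. With p analytes
each sample becomes a complete graph with p nodes and C(p, 2) edges — 4950
at the default p = 100.

Choices where the construction is underdetermined:

* *Calibration.* Platt scaling keeps the score probability-like and keeps
  0.5 as the decision boundary, which the sparsifiers assume. If a training
  class has fewer than 3 samples, or the fitted sigmoid would be
  non-monotone, the plain logistic squash σ(f) of the decision value is used
  instead. A pair whose two features are both constant in training becomes
  the neutral constant-0.5 edge (with a warning).
* *Standardization.* Per-feature location/scale are estimated on the
  training partition only and applied unchanged to validation, test and
  holdout samples, so no held-out information reaches any edge weight.
* *Determinism.* `LinearSVC(dual=False)` and the Newton calibration are
  deterministic; refitting the bank on the same training partition and seed
  reproduces every score bit-for-bit. Each bank carries a fingerprint
  (hash of training sample ids, seed, features) that graph bundles record,
  so graphs cannot silently be mixed with a different bank.

## Sparsification

Edge significance is |w − 0.5|. Three strategies:

* `none` — keep the complete graph;
* `threshold` with fraction p ∈ (0, 1] — keep exactly ⌈p·|E|⌉ edges of
  largest significance. Ties at the cut are resolved lexicographically by
  node-index pair, preserving the exact-count contract deterministically;
* `min_connected` — keep edges with significance ≥ ε*, where ε* is the
  largest threshold at which the graph stays connected. ε* is located by
  binary search on [0, max significance] (tolerance 1e−9, ≤ 60 iterations)
  and then snapped to an actual edge significance inside the converged
  interval, so the returned bound is attained exactly; it equals the
  bottleneck of the maximum-bottleneck spanning tree on significances,
  which the tests verify against two independent brute-force oracles.

## Node descriptors

After sparsification each node i carries f_i = [s, d, st, c, b]: raw
concentration, degree / (|V|−1), strength (sum of retained incident
weights) / (|V|−1), closeness, and betweenness normalized by
(|V|−1)(|V|−2)/2. Centralities are computed on the weighted graph under the
affinity-to-distance transform length = 1/(w + 1e−6): a high-confidence edge
is a short link. Closeness uses the standard per-component correction
c_i = (R_i/Σd)·(R_i/(|V|−1)) with R_i the number of reachable nodes
(isolated node: 0), because threshold sparsification can disconnect the
graph. Betweenness credits equal-length paths fractionally. On the complete
graph with near-uniform weights d ≡ 1 and b ≈ 0, so in the unsparsified
configuration the signal enters mainly through s and st — relevant when
reading the node-feature ablation. The raw-signal-only ablation replaces
f_i by the single column [s]. Centralities are evaluated with igraph's C
implementations; the test suite checks them to 1e−9 (closeness) and exact
path counts (betweenness) against a hand-written Floyd–Warshall/Brandes
oracle and against networkx.

## Graph classifiers

Two architectures, implemented in NumPy on a small reverse-mode autodiff
core (`synolitic.nn.autograd`; gradients are verified against central finite
differences in the test suite):

* **GCN** — two message-passing layers over the symmetrically normalized
  weighted adjacency D̃^{−1/2}(W_masked + I)D̃^{−1/2}, so the calibrated
  edge weight acts directly as the convolution coupling; ReLU, residual
  connections, dropout.
* **GATv2** — two attention layers; per-edge logits
  aᵀ LeakyReLU(W_l h_src + W_r h_dst + W_e e_ij) with a segment softmax over
  each node's incoming edges. The scalar edge weight enters through a
  2-layer, 32-wide edge-encoder MLP (self-loops carry weight 1). With 3
  concatenated heads the layer width is 3 × 128 = 384; residuals project
  when widths differ. The GCN path consumes w_ij as the convolution weight
  and does not use the edge encoder, since a scalar-weighted convolution has
  no slot for a vector edge embedding.

Read-out is mean pooling over nodes (all graphs share the analyte node set),
followed by a 2-layer, 32-wide MLP head emitting one logit per graph.

Reference hyperparameters (defaults of `GNNConfig`): hidden size 128,
2 layers, dropout 0.30, residual connections, 3 attention heads
(concatenated), edge encoder 32×2, classifier head 32×2, Adam with learning
rate 1e−2 and weight decay 1e−5, reduce-on-plateau factor 0.5 / patience 32,
early-stopping patience 128, `max_epochs` 1000. Mixed precision is exposed
as a flag but off by default; everything runs in float64, which is what
makes seeded runs bit-reproducible and node-permutation invariance hold to
<1e−5.

Training protocol choices:

* *Loss* — binary cross-entropy on a single logit; full-batch Adam steps.
  For attention models the batch is processed in graph chunks whose summed
  weighted gradients equal the full-batch gradient exactly (chunking bounds
  the per-edge tensor memory; it does not change the optimization).
* *Monitored validation metric* — validation ROC-AUC, not validation loss.
  On cohorts of this size the validation cross-entropy diverges through
  overconfidence from the first epochs while the ranking is still
  improving, so loss-based stopping would systematically restore the
  initial epoch. The plateau schedule, early stopping and best-epoch
  restoration all follow validation AUC (fallback: negative validation loss
  if the validation split is single-class). Validation loss remains in the
  training history.
* *Feature scaling* — the node-feature columns are standardized with
  statistics from the training graphs only; raw concentrations span orders
  of magnitude across assays and destabilize training at lr 1e−2.

## Evaluation protocol

Patients are split into k = 5 stratified folds (never samples: a patient's
final and penultimate samples move together). Per fold:

1. the held-out patients' final-visit samples form the **Primary Test Set**
   (< 1 year pre-diagnosis window) and their penultimate samples the
   **Early-Detection Holdout Set** (1–2 years);
2. a stratified 20% validation split is carved from the training fold; the
   pair bank, standardizations and models are fitted on the remaining 80%,
   the validation split drives early stopping and threshold selection;
3. the decision threshold maximizes F1 on the validation split (searched
   over midpoints of sorted unique probabilities; degenerate constant
   probabilities fall back to 0.5 with a warning) and is reused unchanged
   on the holdout window;
4. ROC-AUC, F1, sensitivity and specificity are reported per fold on the
   percent scale and aggregated as mean ± sd; a pooled-predictions AUC row
   is emitted for transparency (fold `pooled`).

Baselines (XGBoost, random forest, SVM with sigmoid-calibrated
probabilities, logistic regression, elastic-net logistic regression)
consume the flat per-fold-standardized feature vectors with library-default
hyperparameters and fixed seeds, recorded in the resolved config snapshot.
The training-fraction sweep stratified-subsamples the training side of each
fold to a given fraction, reruns the first grid cell and the first
baseline, and reports the AUC curve; at fraction 1.0 it reproduces the
corresponding grid cell exactly.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes about serum
proteomics panels. Per feature, a log-normal base distribution with
log-mean ~ U(0, 8) and log-sd ~ U(0.3, 0.8) (scales spanning orders of
magnitude, as across mixed immunoassay/panel platforms) and multiplicative
assay noise with CV ~ U(0.04, 0.20), matching the 4–20% intra-assay band of
such panels. Per patient, a latent Gaussian anchor is shared between the
two visits (within-patient correlation 0.5), giving paired final and
penultimate samples.

Disease signal (cases only, scaled by `attenuation` = 0.5 at the
penultimate visit):

* **Signal pairs** (default 8; disjoint analyte pairs): controls carry a
  latent correlation of 0.7; cases reduce it by `pair_effect` (default 0.8)
  *and* shift the pair antisymmetrically by ±`pair_shift` (default
  0.45·pair_effect) along the within-pair contrast. The antisymmetric
  component is deliberately weak marginally but strong relative to the
  correlation-conditioned spread of x_i − x_j — a synergy only a joint
  model of the pair can exploit. A pure correlation flip with identical
  margins was rejected as the planted mechanism because a linear
  two-feature classifier provably cannot detect it (the class-conditional
  means and variances coincide), which would disconnect the generator from
  the edge construction it is meant to exercise.
* **Marginal markers** (default 4): a standardized latent mean shift of
  0.75 in cases, mimicking conventional single-analyte biomarkers.

`make_null_cohort` forces all three effects to zero; labels are then
independent of every feature. `planted_pair_auc` reports the held-out AUC
of a quadratic discriminant on the log concentrations of one planted pair,
the oracle used to verify that planted pairs are detectable but not
trivially separable.

What the generator does **not** emulate: histotype or stage structure,
platform-specific batch effects, missingness (missing cells are a hard
load-time error, as in the cohort contract), censoring, or any real
inter-analyte correlation network beyond the planted pairs. Passing tests
therefore demonstrate that the machinery recovers the kind of signal the
method postulates; they say nothing about how often real serum proteomes
carry such signal.

## Null behavior under p ≫ n

A practical caveat verified during development: with 100 features and 64
samples, the 5-fold mean AUC on a single *null* dataset is far more
variable than binomial intuition suggests. Chance feature–label alignments
of one realized dataset persist across its CV folds, so flexible baselines
can reach single-dataset null CV-AUCs of 30% or 70% depending on the
generator seed (the graph-regularized GNNs stay closer to 50%). The null
calibration test fixes the suite's canonical seed; readers comparing their
own null runs should expect spread of this magnitude rather than a tight
±5-point band.

## Problem sizes used by the test and acceptance runs

The repository's tests and `scripts/acceptance.py` run the same code paths
as a full study but choose economical problem sizes: oracle comparisons use
100 random graphs of 6–12 nodes; the end-to-end grid runs the default
64 × 100 cohort with `max_epochs` 80; the planted-signal recovery run uses
n = 200 final samples with `max_epochs` 150; null calibration uses
`max_epochs` 15 (there is nothing to fit on null data; the protocol is
otherwise unchanged). All remaining defaults are the reference values
above.

## Known limitations

* The GNNs run on CPU in float64; wall time, not memory, is the practical
  limit for attention models on unsparsified 100-node graphs.
* No nested hyperparameter search; Table-defaults and library defaults are
  fixed by design.
* Only the two-visit (final/penultimate) longitudinal structure is
  modelled; no multi-visit trajectories.
* The comparison-graph export ranks pairs by the case-minus-control
  difference in mean edge weight; when the named hub analyte has no edge
  among the top-k pairs, its single best-ranked incident pair is appended
  so the hub is always connected in the exported file.
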