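# Methods

## Model

The classifier is a feed-forward network whose connectivity is data, not a
hyperparameter. A layered topology is compiled from two inputs: a
child→parent pathway relation table (Reactome dialect) and a GMT file of
gene-set membership. The compiled network has one feature layer (three
binary channels per gene: nonsynonymous mutation, high amplification, deep
deletion), one gene layer, and K pathway layers (default K = 5) ordered
from most specific to root. Each consecutive layer pair carries a fixed
binary mask M, and the layer computes

    y = tanh((M ∗ W)ᵀ x + b)

so a trainable weight exists only where a curated relation exists. Masked
entries of W are zeroed at initialisation, receive masked gradients, and
are provably inert: perturbing them never changes a prediction (tested).

Every hidden layer additionally feeds a one-unit sigmoid head. The model's
reported probability is the arithmetic mean of the head outputs; the loss is
the head-weighted sum of class-weighted binary cross-entropies, with
probabilities clipped at 1e−7. Heads give shallow layers a direct training
signal and make each layer interpretable on its own.

### Hierarchy layering

Pathways are placed at their minimum child→parent distance to any root, so
the outermost layer holds the top-level processes. Pathways deeper than K−1
are collapsed: their gene annotations propagate to their nearest retained
ancestors. A retained pathway with genes to receive but no retained child is
bridged to the gene-adjacent layer through identity "copy" nodes, keeping
every mask strictly between adjacent layers. Lateral edges (a parent at the
same or greater depth than its child, possible in a DAG) are dropped; their
count is recorded on the compiled network. One known loss: a mid-level
pathway that has retained children *and* its own direct gene annotation only
receives those direct genes if a child also carries them — in curated
hierarchies annotation is concentrated at the leaves, where no loss occurs.

### Training

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 0.001 multiplied by 0.5
every 50 epochs; batch size 50; 300 epochs by default (the experiments in
this repository use 100, which is past convergence at their problem sizes).
Class weights are balanced inverse frequencies w_c = N/(2 n_c). Head loss
weights default to a geometric ramp (1, 2, 4, …) so later, narrower layers —
which are harder to fit — carry more weight; any non-decreasing user vector
is accepted. When a validation set is supplied, the epoch with the best
validation AUC is restored at the end (ties keep the earlier epoch). No
dropout; an optional L2 penalty on W is exposed and off by default.

**Initialisation.** Weights are Glorot-uniform over the *full* layer shape,
then masked. We deliberately do not scale by the sparse (mask) fan-in:
with three-input gene nodes that limit is ≈1.2, the tanh units start as a
high-variance random feature map, and the model memorises small training
sets — in our experiments it then loses to a parameter-matched dense model,
inverting the sparse architecture's characteristic small-sample advantage.
Full-shape Glorot keeps the network near-linear at the start and restores
that advantage (it is also what standard dense initialisers do).

Training runs on compressed weight vectors (only mask nonzeros) with sparse
matrix products whenever a mask's density is ≤ 25%; this is exactly
equivalent to the dense computation and makes Adam's state proportional to
the number of real parameters.

## Attribution

DeepLIFT with the Rescale rule, implemented directly against the network's
own forward pass. For sample x and reference x0, multipliers flow backwards
like gradients through the masked linear ops, while each nonlinearity f
contributes (f(z) − f(z0))/(z − z0), falling back to f′(z0) when
|z − z0| < 1e−7. A node's contribution is multiplier × (activation −
reference activation).

* **Reference**: the all-zero profile (no genomic alterations) — the
  natural no-event baseline for binary alteration features.
* **Target**: the model's reported quantity, the mean of the head sigmoids.
* **Completeness**: contributions of layer l sum to the part of the target
  difference reachable from layer l (the mean over heads at or above l of
  their probability differences). For the feature and gene layers every head
  is downstream, so the sum equals the full Δt = t − t0. The per-layer
  target differences are reported alongside the scores and the identity
  holds to machine precision (asserted at 1e−4 relative tolerance over 500
  randomized networks).

Aggregate importance is the absolute value of the *signed* sum of
per-sample scores over the evaluation set (default: test samples).
Degree adjustment divides a node's aggregate score by its degree
(fan-in + fan-out, heads excluded) when the degree exceeds its layer's mean
plus five population standard deviations; μ and σ are computed per layer
because degree scales differ by orders of magnitude between the gene and
pathway layers. The adjustment can only decrease a score.

Per-node activation analysis uses Welch's t between the two classes;
constant-activation nodes (e.g. zero fan-in) are flagged degenerate with
statistic 0.

## Evaluation protocol

Stratified 80/10/10 split (test = ceil(0.10 n), validation the same size);
stratified 5-fold CV on the development set. Metrics: tie-corrected
rank-statistic AUC, step-interpolated AUPRC, and accuracy/F1/precision/
recall at the 0.5 cutoff (an undefined precision is reported as 0 and
flagged). AUC differences between paired models use the DeLong test; other
metrics use a bootstrap of the test indices (2,000 resamples by default)
testing the median metric difference, with a doubled two-sided add-one
p-value 2·min(#{d≤0}+1, #{d≥0}+1)/(B+1) — the doubling is what makes the
test reject at ≈5% under the null (verified by permutation at 200
replicates). Families of p-values are Benjamini–Hochberg adjusted. The
learning-curve experiment compares fold-level CV scores between two models
per training size with an equal-variance t-test; identical arms with zero
variance report p = 1. The clinical helpers are a Yates-corrected
chi-squared (continuity correction clamped at zero, so O = E contributes
nothing) and the standard two-group log-rank test (via lifelines).

The balanced-subsample ensemble (external-validation protocol) trains
n members on all minority samples plus equal-size disjoint majority draws
and averages their scores.

## Synthetic cohorts

The generator emulates the *structure* of the real inputs: a layered
pathway tree (default widths 20–5–1 above 200 genes, 10 genes per leaf
pathway; optional DAG cross-edges and gene-set overlap), and a
samples × genes × 3 tensor in which a configurable set of driver leaf
pathways carries the class signal — driver genes are altered with
probability p1 in class-1 samples and p0 elsewhere, each alteration drawn
onto one channel from channel_mix (default 0.5/0.3/0.2
mutation/amplification/deletion, so amplification and deletion never
co-occur, matching GISTIC gene-level calls). Labels are Bernoulli with the
configured class balance (default 0.5).

What it does *not* emulate: real mutation spectra, gene length effects,
co-occurrence/mutual-exclusivity structure, per-sample mutation burden
variation, or annotation noise. Passing tests therefore demonstrate the
machinery (masking, training, attribution, statistics) under a known ground
truth, not clinical performance on real cohorts.

Because channels and background genes carry no class information, the
Bayes-optimal statistic on these cohorts is the count of altered driver
genes, and the exact optimal AUC (Binomial(k, p1) vs Binomial(k, p0)) is
available in closed form as an upper-bound oracle for any trained model.

## Experiment sizes and defaults in this repository

* Sparse-vs-dense comparison: 100 leaf pathways × 10 genes (1,000 genes,
  3,000 features), 5 driver pathways, p1 = 0.3 vs p0 = 0.05, n = 150,
  5-fold CV, five seeds; the dense comparator is a fully connected
  single-hidden-layer network solved to the same total parameter count
  (which at this budget allows only ~2 hidden units — the point of the
  comparison: a dense architecture cannot spend a small budget wisely over
  a wide input).
* Driver recovery: default hierarchy, 3 drivers, p1 = 0.4 vs p0 = 0.02,
  n = 800, five seeds; recovery means ≥2 of 3 drivers in the top-10
  degree-adjusted importances of the leaf-pathway layer.
* Null calibration: 200 permutation replicates, bootstrap at 500 resamples.
* 100 epochs everywhere above; all runs single-CPU and seeded.

## Known limitations

* The layer-collapse and copy-node rules are one consistent choice among
  several the hierarchy inputs admit; node counts on a given Reactome
  release depend on that choice.
* Mutation counts are binarized by default (presence/absence); raw counts
  are available but interact poorly with tanh saturation.
* The attribution target is the averaged outcome; per-head attributions are
  not exposed.
* Baseline SVM scores are sigmoid-squashed decision margins (SVMs are not
  calibrated probability models); ranking metrics are unaffected.
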