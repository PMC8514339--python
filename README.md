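# pnet — pathway-constrained sparse neural networks for cancer genomics

Deep models on tumour genomes usually face a brutal ratio: tens of thousands
of per-gene features against at most a few hundred labelled patients, and a
fitted dense network explains nothing. This package implements the
alternative: a feed-forward classifier whose architecture **is** a curated
biological hierarchy. Every node is a gene or a pathway, every connection an
annotated gene→pathway or child→parent pathway relation, and everything else
is forced to zero by a fixed binary mask. The result has orders of magnitude
fewer parameters than its dense counterpart, performs better at small sample
sizes, and its internal nodes can be read out directly as pathway-level
importance scores.

It is aimed at computational cancer-genomics groups who want to (1) predict
a binary disease state (primary vs metastatic/castration-resistant) from
somatic mutation and copy-number profiles and (2) rank genes and pathways by
their contribution to that prediction.

## The model

Each layer computes

```
y = f[(M ∗ W)ᵀ x + b],        f = tanh
```

where `M` is the binary mask compiled from the hierarchy, `W` the trainable
weights, `∗` the Hadamard product. The input layer has exactly three nodes
per gene — nonsynonymous mutation, high amplification (GISTIC +2), deep
deletion (GISTIC −2) — connected one-to-one to the gene layer; gene→pathway
and pathway→pathway masks follow the annotation. Every hidden layer also
feeds a one-unit sigmoid prediction head; the final score is the mean of the
head probabilities. Training minimises head-weighted, class-weighted binary
cross-entropy (`w_c = N / 2n_c`) with Adam, the learning rate starting at
0.001 and halving every 50 epochs.

Interpretation uses the DeepLIFT Rescale rule: backward-propagated
multipliers assign each node in each layer a per-sample contribution
`C_i^{l,s}` whose layer-wise sum equals the target activation difference
`Δt = t − t0` against an all-zeros (no alteration) reference. Aggregate
importance is `C_i^l = |Σ_s C_i^{l,s}|`, and hub nodes with degree above the
layer mean plus 5σ are down-weighted by their degree.

## Worked example

```python
import numpy as np
from pnet import PNet, TrainingConfig, synthetic
from pnet.evaluation import compute_metrics, make_splits

cohort = synthetic.generate(synthetic.SimulationConfig(
    n_samples=800, p1=0.4, p0=0.02, n_drivers=3, seed=0))
net = cohort.build_network()
X, y = cohort.tensor.flatten(), cohort.y
split = make_splits(y, seed=0)

model = PNet(X[split.train], y[split.train], net,
             config=TrainingConfig(epochs=100, seed=0))
res = model.fit(validation=(X[split.validation], y[split.validation]))
print(res.summary())
print("test AUC:", compute_metrics(
    y[split.test], res.predict(X[split.test]).pnet_score).auc)

scores = res.explain(X[split.test])
adj = scores.adjusted()
names = scores.node_names[2]               # leaf pathway layer
top = sorted(zip(adj[2], names))[-3:]
print("top pathways:", [n for _, n in top])
print("planted drivers:", cohort.driver_pathways)
```

prints

```
P-NET results
==============================================
layers (nodes):        600 -> 200 -> 20 -> 5 -> 1
trainable parameters:  1281
dense equivalent:      124561
heads:                 4
epochs trained:        100
final training loss:   1.1632
best validation AUC:   1.0000
==============================================
test AUC: 1.0
top pathways: ['R-HSA-SYN-L0N015', 'R-HSA-SYN-L0N009', 'R-HSA-SYN-L0N008']
planted drivers: ('R-HSA-SYN-L0N008', 'R-HSA-SYN-L0N009', 'R-HSA-SYN-L0N015')
```

— the masked model needs ~1% of the dense parameter count, separates the
cohort perfectly at this effect size, and the degree-adjusted DeepLIFT
ranking returns exactly the three pathways the simulator planted.

Real data enter through the same path: `parse_relations` /
`parse_gmt` compile a Reactome-dialect hierarchy, `load_mutations` (MAF or
matrix), `load_cnv` (GISTIC calls) and `assemble_profiles` build the tensor.
A `pnet` command-line tool wraps the workflow
(`pnet simulate | train | evaluate | explain`).

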