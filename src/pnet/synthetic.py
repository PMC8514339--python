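"""Synthetic pathway hierarchies and genomic cohorts with planted signal.

The generator emulates the structure the real inputs have — a layered
pathway hierarchy (Reactome-like tree, optionally with extra cross edges),
leaf-pathway gene sets, and a samples x genes x 3 alteration tensor — while
planting a known ground truth: a handful of "driver" leaf pathways whose
member genes are altered with probability ``p1`` in class-1 (metastatic)
samples and ``p0`` everywhere else.  Because the drivers are known, driver
recovery by attribution and the sparse-versus-dense comparison become
testable without any external download.

Alterations are assigned one channel each (mutation / amplification /
deletion, drawn from ``channel_mix``), so amplification and deletion are
never simultaneous for the same (sample, gene) — matching GISTIC gene-level
calls.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import CohortLabels, ProfileTensor
from .hierarchy import GeneSetCollection, HierarchyGraph, build_layered_network

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_hierarchy",
    "generate_cohort",
    "generate",
    "write_fixture",
    "read_fixture",
    "bayes_optimal_auc",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``layer_widths`` counts pathways per layer ordered from the
    gene-adjacent layer to the root layer; the defaults (20 leaf pathways of
    10 genes each under 5 mid-level pathways and one root, 500 samples,
    p1 = 0.3 vs p0 = 0.05 background, balanced classes) give a desk-scale
    cohort with a clearly plantable but noisy pathway-level signal.
    """

    layer_widths: tuple = (20, 5, 1)  # gene-adjacent -> root
    children_per_parent: int = 5
    genes_per_leaf_pathway: int = 10
    n_samples: int = 500
    n_drivers: int = 3
    p1: float = 0.3
    p0: float = 0.05
    channel_mix: tuple = (0.5, 0.3, 0.2)  # mutation, amplification, deletion
    class_balance: float = 0.5
    cross_edge_rate: float = 0.0
    gene_overlap_rate: float = 0.0
    id_prefix: str = "R-HSA-SYN"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p0 <= self.p1 <= 1.0):
            raise ValueError("require 0 <= p0 <= p1 <= 1")
        if abs(sum(self.channel_mix) - 1.0) > 1e-9:
            raise ValueError("channel_mix must sum to 1")
        if any(w <= 0 for w in self.layer_widths):
            raise ValueError("layer widths must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")

    def with_(self, **kw):
        return replace(self, **kw)


@dataclass
class SyntheticCohort:
    """Generated hierarchy + profiles + labels + ground truth."""

    graph: HierarchyGraph
    genesets: GeneSetCollection
    tensor: ProfileTensor
    labels: CohortLabels
    driver_pathways: tuple
    driver_genes: frozenset
    config: SimulationConfig

    def build_network(self, n_pathway_layers=None):
        K = n_pathway_layers or len(self.config.layer_widths)
        return build_layered_network(self.graph, self.genesets, n_pathway_layers=K)

    @property
    def y(self):
        return self.labels.vector(self.tensor.samples)


def _pathway_id(config, layer, index):
    return f"{config.id_prefix}-L{layer}N{index:03d}"


def generate_hierarchy(config):
    """Rooted layered tree (plus optional cross edges) with leaf gene sets.

    Deterministic given ``config.seed``.  Layer 0 is gene-adjacent; the last
    layer holds the roots.  Each leaf pathway receives a disjoint block of
    ``genes_per_leaf_pathway`` genes; with ``gene_overlap_rate`` each leaf
    additionally borrows genes from other leaves.
    """
    rng = np.random.default_rng(config.seed)
    widths = list(config.layer_widths)
    for lower, upper in zip(widths[:-1], widths[1:]):
        if int(np.ceil(lower / upper)) > config.children_per_parent:
            raise ValueError(
                f"cannot place {lower} children under {upper} parents with "
                f"children_per_parent={config.children_per_parent}"
            )

    nodes = [
        [_pathway_id(config, l, i) for i in range(w)] for l, w in enumerate(widths)
    ]
    edges = []
    for l in range(len(widths) - 1):
        children = list(rng.permutation(nodes[l]))
        parents = nodes[l + 1]
        for i, c in enumerate(children):
            edges.append((c, parents[i % len(parents)]))
        if config.cross_edge_rate > 0:
            for c in nodes[l]:
                if rng.random() < config.cross_edge_rate:
                    edges.append((c, parents[int(rng.integers(len(parents)))]))

    names = {}
    for l, layer_nodes in enumerate(nodes):
        for i, p in enumerate(layer_nodes):
            names[p] = f"Synthetic pathway layer {l} #{i}"
    graph = HierarchyGraph(
        pathway_ids=frozenset(x for layer in nodes for x in layer),
        edges=tuple(sorted(set(edges))),
        display_names=names,
    )

    g_per = config.genes_per_leaf_pathway
    n_genes = widths[0] * g_per
    width_digits = len(str(max(n_genes - 1, 1)))
    gene_names = [f"G{i:0{width_digits}d}" for i in range(n_genes)]
    membership = {}
    for i, leaf in enumerate(nodes[0]):
        genes = set(gene_names[i * g_per : (i + 1) * g_per])
        if config.gene_overlap_rate > 0:
            others = [g for g in gene_names if g not in genes]
            for g in others:
                if rng.random() < config.gene_overlap_rate / len(others):
                    genes.add(g)
        membership[leaf] = frozenset(genes)
    return graph, GeneSetCollection(membership=membership)


def generate_cohort(graph, genesets, config):
    """Draw labels and alteration profiles with planted driver pathways."""
    rng = np.random.default_rng(config.seed + 1)
    leaves = sorted(
        p for p in graph.pathway_ids if p not in {e[1] for e in graph.edges}
    )
    annotated_leaves = [p for p in leaves if p in genesets.membership]
    if config.n_drivers > len(annotated_leaves):
        raise ValueError(
            f"n_drivers={config.n_drivers} exceeds {len(annotated_leaves)} leaf pathways"
        )
    drivers = tuple(
        sorted(str(p) for p in rng.choice(annotated_leaves, size=config.n_drivers, replace=False))
    )
    driver_genes = frozenset().union(*(genesets.membership[p] for p in drivers))

    genes = sorted(genesets.genes())
    n, g = config.n_samples, len(genes)
    digits = len(str(max(n - 1, 1)))
    samples = [f"S{i:0{digits}d}" for i in range(n)]
    y = (rng.random(n) < config.class_balance).astype(np.int64)

    is_driver = np.array([gene in driver_genes for gene in genes])
    p = np.full((n, g), config.p0)
    p[np.ix_(y == 1, is_driver)] = config.p1
    altered = rng.random((n, g)) < p
    channel = rng.choice(3, size=(n, g), p=list(config.channel_mix))

    values = np.zeros((n, g, 3))
    for k in range(3):
        values[:, :, k] = altered & (channel == k)

    tensor = ProfileTensor(samples=samples, genes=genes, values=values)
    labels = CohortLabels(labels={s: int(v) for s, v in zip(samples, y)})
    return SyntheticCohort(
        graph=graph,
        genesets=genesets,
        tensor=tensor,
        labels=labels,
        driver_pathways=drivers,
        driver_genes=driver_genes,
        config=config,
    )


def generate(config=None, **kw):
    """One-call generator: hierarchy + cohort from a config (or overrides)."""
    if config is None:
        config = SimulationConfig(**kw)
    elif kw:
        config = config.with_(**kw)
    graph, genesets = generate_hierarchy(config)
    return generate_cohort(graph, genesets, config)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(cohort, outdir):
    """Write the cohort in the exact flat-file dialects the loaders read.

    Emits ``relations.tsv`` (child, parent), ``pathway_names.tsv``,
    ``pathways.gmt``, ``mutations.csv`` and ``cnv.csv`` (genes x samples),
    ``labels.csv`` and ``truth.csv`` (driver pathways/genes).  Byte-level
    deterministic given the cohort.
    """
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "relations.tsv"), "w") as fh:
        for c, p in cohort.graph.edges:
            fh.write(f"{c}\t{p}\n")
    with open(os.path.join(outdir, "pathway_names.tsv"), "w") as fh:
        for p in sorted(cohort.graph.pathway_ids):
            fh.write(f"{p}\t{cohort.graph.display_names.get(p, p)}\n")
    with open(os.path.join(outdir, "pathways.gmt"), "w") as fh:
        for p in sorted(cohort.genesets.membership):
            genes = "\t".join(sorted(cohort.genesets.membership[p]))
            fh.write(f"{p}\tsynthetic\t{genes}\n")

    t = cohort.tensor
    mut = pd.DataFrame(t.values[:, :, 0].T.astype(int), index=t.genes, columns=t.samples)
    cnv = pd.DataFrame(
        (2 * t.values[:, :, 1] - 2 * t.values[:, :, 2]).T.astype(int),
        index=t.genes,
        columns=t.samples,
    )
    mut.to_csv(os.path.join(outdir, "mutations.csv"))
    cnv.to_csv(os.path.join(outdir, "cnv.csv"))
    pd.DataFrame(
        {"sample_id": t.samples, "response": [cohort.labels.labels[s] for s in t.samples]}
    ).to_csv(os.path.join(outdir, "labels.csv"), index=False)
    pd.DataFrame(
        {
            "kind": ["pathway"] * len(cohort.driver_pathways)
            + ["gene"] * len(cohort.driver_genes),
            "id": list(cohort.driver_pathways) + sorted(cohort.driver_genes),
        }
    ).to_csv(os.path.join(outdir, "truth.csv"), index=False)
    return outdir


def read_fixture(outdir, config=None):
    """Re-ingest a written fixture through the ordinary loaders.

    Returns ``(net, tensor, labels, graph, genesets)``; the tensor is
    assembled against the re-compiled network, so a round trip exercises the
    whole ingestion path.
    """
    from .genomics_io import assemble_profiles, load_cnv, load_labels, load_mutations
    from .hierarchy import parse_gmt, parse_pathway_names, parse_relations

    prefix = (config or SimulationConfig()).id_prefix
    names = parse_pathway_names(os.path.join(outdir, "pathway_names.tsv"))
    graph = parse_relations(
        os.path.join(outdir, "relations.tsv"), species_prefix=prefix, display_names=names
    )
    genesets = parse_gmt(os.path.join(outdir, "pathways.gmt"))
    n_layers = len({p for p in graph.pathway_ids}) and _n_layers_from_ids(graph)
    net = build_layered_network(graph, genesets, n_pathway_layers=n_layers)
    mut = load_mutations(os.path.join(outdir, "mutations.csv"), dialect="matrix")
    cnv = load_cnv(os.path.join(outdir, "cnv.csv"))
    labels = load_labels(os.path.join(outdir, "labels.csv"))
    tensor = assemble_profiles(mut, cnv, net, binarize_mutations=True)
    return net, tensor, labels, graph, genesets


def _n_layers_from_ids(graph):
    layers = {int(p.split("-L")[-1].split("N")[0]) for p in graph.pathway_ids}
    return max(layers) + 1


# ---------------------------------------------------------------------------
# analytic oracle


def bayes_optimal_auc(n_driver_genes, p1, p0):
    """Exact AUC of the Bayes-optimal classifier on a planted cohort.

    Channels and non-driver genes carry no class information, so the optimal
    statistic is the count of altered driver genes: Binomial(k, p1) for
    class 1 versus Binomial(k, p0) for class 0.  AUC = P(S1 > S0) +
    P(S1 = S0) / 2, computed from the exact binomial pmfs.
    """
    k = int(n_driver_genes)
    s = np.arange(k + 1)
    f1 = stats.binom.pmf(s, k, p1)
    f0 = stats.binom.pmf(s, k, p0)
    cdf0 = np.cumsum(f0)
    p_gt = float(np.sum(f1[1:] * cdf0[:-1]))
    p_eq = float(np.sum(f1 * f0))
    return p_gt + 0.5 * p_eq
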