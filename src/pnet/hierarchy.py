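"""Compile a curated pathway hierarchy into a layered, masked network topology.

The architecture of a pathway-constrained network is fully determined by data:
a child->parent pathway relation table (Reactome dialect), a GMT file mapping
pathways to member genes, and the number of pathway layers to retain.  This
module parses those inputs and produces a :class:`LayeredNetwork`: an ordered
list of node layers (features, genes, then pathway layers from most specific
to root) together with one binary mask matrix per consecutive layer pair.
The masks are what make the downstream model sparse: a weight exists only
where a curated biological relation exists.

Layering rule
-------------
Each pathway is placed once, at its minimum child->parent distance to any
root (roots sit in the last layer).  Pathways deeper than the number of
retained layers are collapsed: their gene annotations propagate up to their
nearest retained ancestors.  A retained pathway with no retained child is
bridged down to the gene-adjacent layer through identity "copy" nodes so
that every mask connects adjacent layers only.
"""

from __future__ import annotations

import io
import os
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "HierarchyGraph",
    "GeneSetCollection",
    "LayeredNetwork",
    "ParamCount",
    "parse_relations",
    "parse_gmt",
    "build_layered_network",
    "count_params",
    "node_degrees",
    "degrees_by_layer",
]

COPY_SEP = "::copy"


class HierarchyError(ValueError):
    """Raised for malformed or inconsistent hierarchy inputs."""


@dataclass(frozen=True)
class HierarchyGraph:
    """A directed acyclic child->parent pathway graph.

    Attributes
    ----------
    pathway_ids : frozenset of str
        All known pathway identifiers (union of edge endpoints).
    edges : tuple of (str, str)
        Deduplicated ``(child, parent)`` pairs, lexicographically sorted.
    display_names : dict
        Optional ``pathway_id -> human readable name``.
    """

    pathway_ids: frozenset
    edges: tuple
    display_names: dict = field(default_factory=dict)

    @property
    def roots(self):
        """Pathways that never appear as a child (no parent), sorted."""
        children = {c for c, _ in self.edges}
        return sorted(p for p in self.pathway_ids if p not in children)

    @property
    def n_pathways(self):
        return len(self.pathway_ids)

    def children_of(self, parent):
        return sorted(c for c, p in self.edges if p == parent)

    def to_networkx(self):
        """Child->parent edges as a :class:`networkx.DiGraph`."""
        g = nx.DiGraph()
        g.add_nodes_from(self.pathway_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class GeneSetCollection:
    """Pathway -> member-gene mapping parsed from a GMT file."""

    membership: dict  # pathway_id -> frozenset of gene symbols

    def genes(self):
        out = set()
        for s in self.membership.values():
            out |= s
        return out

    def __len__(self):
        return len(self.membership)


@dataclass
class LayeredNetwork:
    """The compiled topology: ordered node layers plus per-pair binary masks.

    ``layers[0]`` is the feature layer (three nodes per gene, named
    ``<GENE>_mut``, ``<GENE>_amp``, ``<GENE>_del``), ``layers[1]`` the gene
    layer, and ``layers[2:]`` the pathway layers ordered from most specific
    (gene-adjacent) to root.  ``masks[l-1]`` has shape ``(n_{l-1}, n_l)`` and
    contains only 0/1.
    """

    layers: list  # list[list[str]]
    masks: list  # list[np.ndarray], masks[i]: layers[i] -> layers[i+1]
    display_names: dict = field(default_factory=dict)

    @property
    def n_l(self):
        return [len(layer) for layer in self.layers]

    @property
    def genes(self):
        return list(self.layers[1])

    @property
    def n_layers(self):
        return len(self.layers)

    def display(self, node_id):
        base = node_id.split(COPY_SEP)[0]
        return self.display_names.get(base, base)

    def validate(self):
        """Check structural invariants; raise :class:`HierarchyError` on failure."""
        if len(self.masks) != len(self.layers) - 1:
            raise HierarchyError("mask count must be len(layers) - 1")
        for i, m in enumerate(self.masks):
            expect = (len(self.layers[i]), len(self.layers[i + 1]))
            if m.shape != expect:
                raise HierarchyError(f"mask {i} shape {m.shape} != {expect}")
            vals = np.unique(m)
            if not np.all(np.isin(vals, [0, 1])):
                raise HierarchyError(f"mask {i} contains non-binary values")
        # feature->gene: exactly 3 features per gene, each feature one gene
        m0 = self.masks[0]
        if not np.all(m0.sum(axis=0) == 3):
            raise HierarchyError("each gene must connect to exactly 3 feature nodes")
        if not np.all(m0.sum(axis=1) == 1):
            raise HierarchyError("each feature node must feed exactly one gene")
        # every non-top pathway node needs a parent-ward connection
        for i in range(2, len(self.layers) - 1):
            out = self.masks[i].sum(axis=1)
            if np.any(out == 0):
                j = int(np.argmin(out))
                raise HierarchyError(
                    f"pathway node {self.layers[i][j]} has no outgoing connection"
                )
        return self


@dataclass(frozen=True)
class ParamCount:
    """Trainable-parameter accounting for a layered network.

    ``per_layer[l]`` is a ``(sparse, dense)`` pair for the l-th non-input
    layer; totals include one dense prediction head (``n_l + 1`` weights) per
    hidden layer when heads are enabled.  ``hybrid_total`` counts a network
    whose first layer keeps the mask and all later layers are dense.
    """

    sparse_total: int
    dense_total: int
    hybrid_total: int
    per_layer: tuple  # ((sparse, dense), ...)

    def __post_init__(self):
        if self.sparse_total > self.dense_total:
            raise ValueError("sparse count cannot exceed dense count")


# ---------------------------------------------------------------------------
# parsing


def _open_maybe(source):
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rt", encoding="utf-8")
    if isinstance(source, io.IOBase) or hasattr(source, "readline"):
        return source
    raise TypeError(f"unsupported source type: {type(source)!r}")


def parse_relations(source, species_prefix="R-HSA", display_names=None):
    """Parse a headerless two-column child->parent relation table.

    Parameters
    ----------
    source : path or file-like or iterable of (child, parent)
        Reactome ``ReactomePathwaysRelation.txt`` dialect: tab-separated,
        two identifier columns per row.
    species_prefix : str or None
        Keep only edges where both identifiers start with this prefix
        (Reactome human is ``"R-HSA"``).  ``None`` disables filtering.
    display_names : dict, optional
        ``pathway_id -> display name`` attached to the graph.

    Returns
    -------
    HierarchyGraph

    Raises
    ------
    HierarchyError
        On a malformed row (with its line number) or if the filtered graph
        contains a cycle (naming one cycle).
    """
    rows = []
    if isinstance(source, (list, tuple)):
        for i, rec in enumerate(source, start=1):
            if len(rec) != 2 or not rec[0] or not rec[1]:
                raise HierarchyError(f"malformed relation record at position {i}: {rec!r}")
            rows.append((str(rec[0]).strip(), str(rec[1]).strip()))
    else:
        fh = _open_maybe(source)
        try:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n\r")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                    raise HierarchyError(f"malformed relation row at line {i}: {line!r}")
                rows.append((parts[0].strip(), parts[1].strip()))
        finally:
            if fh is not source:
                fh.close()

    # Reactome convention is (parent, child) in the relation file, but the
    # graph is declared child->parent here; callers pass pairs accordingly.
    if species_prefix is not None:
        rows = [
            (c, p)
            for c, p in rows
            if c.startswith(species_prefix) and p.startswith(species_prefix)
        ]
    edges = tuple(sorted(set(rows)))
    ids = frozenset(x for e in edges for x in e)

    g = nx.DiGraph(edges)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle is not None:
        path = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
        raise HierarchyError(f"pathway relation cycle detected: {path}")

    return HierarchyGraph(
        pathway_ids=ids, edges=edges, display_names=dict(display_names or {})
    )


def parse_pathway_names(source):
    """Parse a two-column tab-separated (id, display name) table into a dict."""
    names = {}
    fh = _open_maybe(source)
    try:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise HierarchyError(f"malformed names row at line {i}: {line!r}")
            names[parts[0].strip()] = parts[1].strip()
    finally:
        if fh is not source:
            fh.close()
    return names


def normalize_gene(symbol):
    """Gene symbol normalization: uppercase, surrounding whitespace stripped."""
    return str(symbol).strip().upper()


def parse_gmt(source):
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated; symbols are normalized to
    upper case.  A line with fewer than three fields raises
    :class:`HierarchyError` with the line number.
    """
    membership = {}
    fh = _open_maybe(source)
    try:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise HierarchyError(f"GMT line {i} has fewer than 3 fields")
            name = parts[0].strip()
            genes = frozenset(normalize_gene(g) for g in parts[2:] if g.strip())
            if name in membership:
                genes = membership[name] | genes
            membership[name] = genes
    finally:
        if fh is not source:
            fh.close()
    return GeneSetCollection(membership=membership)


# ---------------------------------------------------------------------------
# layering


def _min_depth_to_root(graph):
    """Shortest child->parent distance to any root; roots have depth 0."""
    parents_to_children = {}
    for c, p in graph.edges:
        parents_to_children.setdefault(p, []).append(c)
    depth = {r: 0 for r in graph.roots}
    q = deque(graph.roots)
    while q:
        p = q.popleft()
        for c in parents_to_children.get(p, ()):
            if c not in depth:
                depth[c] = depth[p] + 1
                q.append(c)
    return depth


def _propagated_membership(graph, genesets):
    """For every pathway: its own genes plus all descendants' genes.

    Computed by reverse-topological accumulation over parent->child edges;
    this is the brute-force notion of "genes under a pathway" and is
    independent of the layering that follows.
    """
    g = graph.to_networkx()  # child -> parent
    own = {p: set(genesets.membership.get(p, ())) for p in graph.pathway_ids}
    prop = {p: set(s) for p, s in own.items()}
    # child->parent topological order visits children before parents
    for node in nx.topological_sort(g):
        for parent in g.successors(node):
            prop[parent] |= prop[node]
    return {p: frozenset(s) for p, s in prop.items()}


def build_layered_network(
    graph, genesets, n_pathway_layers=5, gene_universe=None
):
    """Compile hierarchy + gene sets into a :class:`LayeredNetwork`.

    Parameters
    ----------
    graph : HierarchyGraph
    genesets : GeneSetCollection
    n_pathway_layers : int
        Number of retained pathway layers (default five, matching the usual
        Reactome truncation).  Pathways farther than this from a root are
        collapsed into their nearest retained ancestors.
    gene_universe : iterable of str, optional
        If given, the gene layer is restricted to this set (after symbol
        normalization) intersected with the genes covered by the hierarchy.

    Returns
    -------
    LayeredNetwork
        Layers: ``[features, genes, L2(most specific) ... L(1+K)(roots)]``.

    Raises
    ------
    HierarchyError
        If no gene overlaps any gene set after filtering ("empty gene layer").
    """
    if n_pathway_layers < 1:
        raise ValueError("n_pathway_layers must be >= 1")
    K = int(n_pathway_layers)

    universe = None
    if gene_universe is not None:
        universe = {normalize_gene(g) for g in gene_universe}

    # orphan gene sets (pathways absent from the relation graph) form
    # depth-0 singletons only if the graph itself is empty; otherwise they
    # are ignored — connectivity must come from the curated relations.
    if not graph.pathway_ids:
        # degenerate case: no relations; treat every annotated pathway as a
        # single root layer directly over the genes.
        if K != 1 or not genesets.membership:
            raise HierarchyError("empty gene layer: no pathway hierarchy")

    depth = _min_depth_to_root(graph)
    prop = _propagated_membership(graph, genesets)

    def restricted(s):
        return s if universe is None else frozenset(s & universe)

    # retained pathways: depth <= K-1 and at least one gene somewhere below
    retained = {
        p for p in graph.pathway_ids
        if p in depth and depth[p] <= K - 1 and restricted(prop[p])
    }
    if not graph.pathway_ids and genesets.membership:
        retained = set(genesets.membership)
        depth = {p: 0 for p in retained}
        prop = {p: frozenset(genesets.membership[p]) for p in retained}
        retained = {p for p in retained if restricted(prop[p])}

    if not retained:
        raise HierarchyError("empty gene layer: no retained pathway covers any gene")

    # effective gene set at the specific end: own annotation plus annotation
    # of collapsed (deeper-than-K) descendants.  Computed as propagated
    # membership minus what is delivered through retained children.
    slot = {p: K - 1 - depth[p] for p in retained}
    adjacent_children = {p: [] for p in retained}
    n_dropped = 0
    for c, p in graph.edges:
        if c in retained and p in retained:
            if depth[p] == depth[c] - 1:
                adjacent_children[p].append(c)
            else:
                n_dropped += 1  # lateral/backward edge under min-depth layering

    def effective_gene_set(p):
        """Genes a pathway must receive directly (not via retained children)."""
        via_children = set()
        for c in adjacent_children[p]:
            via_children |= prop[c]
        return restricted(frozenset(prop[p] - via_children))

    eff = {p: effective_gene_set(p) for p in retained}

    # node lists per slot (0 = gene-adjacent ... K-1 = roots)
    slot_nodes = [[] for _ in range(K)]
    for p in sorted(retained):
        slot_nodes[slot[p]].append(p)

    # copy chains: pathway at slot s with genes to receive below it gets an
    # identity chain through slots s-1 .. 0 carrying its effective gene set.
    edges_by_slot = [[] for _ in range(K - 1)]  # (child_node, parent_node) at slot s->s+1
    slot0_geneset = {}  # slot-0 node id -> gene set it exposes
    for p in sorted(retained):
        s = slot[p]
        for c in sorted(adjacent_children[p]):
            edges_by_slot[s - 1].append((c, p))
        if s == 0:
            slot0_geneset[p] = eff[p]
        elif eff[p]:
            prev = p
            for k in range(s - 1, -1, -1):
                cp = f"{p}{COPY_SEP}{k}"
                slot_nodes[k].append(cp)
                edges_by_slot[k].append((cp, prev))
                prev = cp
            slot0_geneset[prev] = eff[p]

    for k in range(K):
        slot_nodes[k] = sorted(slot_nodes[k])

    gene_layer = sorted(set().union(*slot0_geneset.values()) if slot0_geneset else set())
    if not gene_layer:
        raise HierarchyError("empty gene layer: no gene overlaps any gene set")

    feature_layer = [f"{g}_{ch}" for g in gene_layer for ch in ("mut", "amp", "del")]

    layers = [feature_layer, gene_layer] + slot_nodes

    # masks
    masks = []
    m0 = np.zeros((len(feature_layer), len(gene_layer)), dtype=np.uint8)
    for j in range(len(gene_layer)):
        m0[3 * j : 3 * j + 3, j] = 1
    masks.append(m0)

    gene_index = {g: i for i, g in enumerate(gene_layer)}
    m1 = np.zeros((len(gene_layer), len(slot_nodes[0])), dtype=np.uint8)
    for j, node in enumerate(slot_nodes[0]):
        for g in slot0_geneset.get(node, ()):
            if g in gene_index:
                m1[gene_index[g], j] = 1
    masks.append(m1)

    for s in range(K - 1):
        lower = {n: i for i, n in enumerate(slot_nodes[s])}
        upper = {n: i for i, n in enumerate(slot_nodes[s + 1])}
        m = np.zeros((len(lower), len(upper)), dtype=np.uint8)
        for c, p in edges_by_slot[s]:
            m[lower[c], upper[p]] = 1
        masks.append(m)

    net = LayeredNetwork(
        layers=layers, masks=masks, display_names=dict(graph.display_names)
    )
    net.n_dropped_edges = n_dropped
    return net.validate()


# ---------------------------------------------------------------------------
# accounting


def count_params(net, include_bias=True, include_heads=True):
    """Count trainable parameters of the masked model and its dense twin.

    The dense count per non-input layer follows ``w_l = n_l * (n_{l-1} + 1)``
    (the +1 is the bias, dropped when ``include_bias`` is false); the sparse
    count is the number of mask ones plus ``n_l`` biases.  With
    ``include_heads`` each hidden layer contributes one dense prediction head
    of ``n_l + 1`` weights to every total.  ``hybrid_total`` keeps only the
    first (feature->gene) layer sparse.
    """
    n = net.n_l
    b = 1 if include_bias else 0
    per_layer = []
    sparse_total = dense_total = hybrid_total = 0
    for l in range(1, len(n)):
        dense = n[l] * (n[l - 1] + b)
        sparse = int(net.masks[l - 1].sum()) + b * n[l]
        per_layer.append((sparse, dense))
        sparse_total += sparse
        dense_total += dense
        hybrid_total += sparse if l == 1 else dense
        if include_heads:
            head = n[l] + 1
            sparse_total += head
            dense_total += head
            hybrid_total += head
    return ParamCount(
        sparse_total=sparse_total,
        dense_total=dense_total,
        hybrid_total=hybrid_total,
        per_layer=tuple(per_layer),
    )


def degrees_by_layer(net):
    """Per-layer arrays of node degrees d = fan_in + fan_out (heads excluded)."""
    out = []
    for l, layer in enumerate(net.layers):
        fan_in = (
            net.masks[l - 1].sum(axis=0).astype(np.int64) if l > 0 else np.zeros(len(layer), dtype=np.int64)
        )
        fan_out = (
            net.masks[l].sum(axis=1).astype(np.int64)
            if l < len(net.masks)
            else np.zeros(len(layer), dtype=np.int64)
        )
        out.append(fan_in + fan_out)
    return out


def node_degrees(net):
    """Degree of every node, ``{node_id: fan_in + fan_out}``."""
    result = {}
    for layer, degs in zip(net.layers, degrees_by_layer(net)):
        for node, d in zip(layer, degs):
            result[node] = int(d)
    return result


def export_network(net, outdir):
    """Write node lists and sparse mask triplets as CSV files under *outdir*."""
    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for l, layer in enumerate(net.layers):
        for node in layer:
            rows.append({"node_id": node, "layer": l, "display_name": net.display(node)})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "nodes.csv"), index=False)
    triplets = []
    for l, m in enumerate(net.masks):
        rr, cc = np.nonzero(m)
        for r, c in zip(rr, cc):
            triplets.append(
                {"row_node": net.layers[l][r], "col_node": net.layers[l + 1][c], "value": 1}
            )
    pd.DataFrame(triplets).to_csv(os.path.join(outdir, "masks.csv"), index=False)
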