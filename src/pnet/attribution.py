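"""DeepLIFT (Rescale rule) node importance through every layer of the model.

For a sample ``x`` and a reference input ``x0``, each node receives a
contribution ``C = m * (a - a0)`` where ``m`` is its multiplier to the
target and ``a``/``a0`` its activations under the sample and the reference.
Multipliers propagate backwards exactly like gradients through the linear
(masked) operations, while each nonlinearity ``f`` contributes the rescale
factor ``(f(z) - f(z0)) / (z - z0)`` — falling back to the derivative
``f'(z0)`` when ``|z - z0|`` is below 1e-7.  The target explained here is
the model's reported quantity: the mean of the per-layer head sigmoids.

Completeness holds per layer: the contributions of layer ``l`` sum to the
part of the target difference that is reachable from layer ``l``, i.e. the
mean over heads at or above ``l`` of their probability differences.  For the
feature and gene layers every head is downstream, so the sum equals the full
target difference ``t - t0``.

Aggregate importance over an evaluation set is the absolute value of the
*signed* sum of sample scores; a node whose degree exceeds its layer's mean
degree by more than five standard deviations has its aggregate divided by
the degree, countering over-annotation bias of hub pathways.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import MaskedNet, sigmoid

__all__ = [
    "AttributionTarget",
    "ImportanceScores",
    "ActivationProfile",
    "deeplift_scores",
    "aggregate_importance",
    "adjust_importance",
    "node_activation_analysis",
    "export_importance_report",
]

RESCALE_EPS = 1e-7


@dataclass
class AttributionTarget:
    """What the scores explain: the averaged outcome on sample vs reference."""

    reference: np.ndarray  # x0, shape (n_features,)
    t: np.ndarray  # target activation per sample
    t0: float  # target activation on the reference

    @property
    def delta_t(self):
        return self.t - self.t0


@dataclass
class ImportanceScores:
    """Sample-level and aggregate DeepLIFT scores for every layer.

    ``sample_scores[l]`` has shape (n_samples, n_l) for activation layer l
    (0 = features, 1 = genes, 2.. = pathway layers); ``delta_t[l]`` is the
    per-sample target difference reachable from that layer, which the layer's
    scores sum to.
    """

    sample_scores: list  # list of (n_samples, n_l) arrays
    delta_t: list  # list of (n_samples,) arrays
    target: AttributionTarget
    node_names: list | None = None  # list of lists, aligned with layers
    degrees: list | None = None  # list of int arrays per layer

    @property
    def n_layers(self):
        return len(self.sample_scores)

    def aggregate(self):
        """Total node importance C_i^l = |sum over samples of C_i^{l,s}|."""
        return [aggregate_importance(s) for s in self.sample_scores]

    def adjusted(self):
        """Degree-adjusted aggregate importance (requires degrees)."""
        if self.degrees is None:
            raise ValueError("degrees not attached to these scores")
        return [
            adjust_importance(C, d) for C, d in zip(self.aggregate(), self.degrees)
        ]


def _rescale(f_z, f_z0, z, z0, deriv_at_z0):
    """Rescale multiplier with the near-zero-difference fallback."""
    dz = z - z0
    small = np.abs(dz) < RESCALE_EPS
    safe = np.where(small, 1.0, dz)
    return np.where(small, deriv_at_z0, (f_z - f_z0) / safe)


def deeplift_scores(fitted, X, reference=None):
    """Sample-level DeepLIFT rescale contributions for all layers.

    Parameters
    ----------
    fitted : PNetResults or MaskedNet
        A trained model.
    X : array (n_samples, n_features)
        Samples to explain.
    reference : array, optional
        Baseline input x0; defaults to the all-zero profile (no genomic
        alterations), the natural no-event baseline for these features.

    Returns
    -------
    ImportanceScores
    """
    if isinstance(fitted, MaskedNet):
        net, model = fitted, None
    else:
        net, model = fitted.net, fitted.model
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, d = X.shape
    if reference is None:
        reference = np.zeros(d)
    x0 = np.asarray(reference, dtype=np.float64).reshape(1, d)

    for layer in net.layers:
        if not np.all(np.isfinite(layer.W)):
            raise ValueError("model has non-finite weights; train before attributing")

    fwd = net.forward(X)
    ref = net.forward(x0)
    H = net.n_heads
    t = fwd["score"]
    t0 = float(ref["score"][0])

    n_act_layers = len(net.layers) + 1  # input + hidden layers
    mult = [np.zeros_like(a) for a in fwd["a"]]

    # heads: target = (1/H) sum_h head(u_h); rescale through each head
    for h in range(H):
        u, u0 = fwd["u"][h], ref["u"][h][0]
        p, p0 = fwd["p"][h], float(ref["p"][h][0])
        if net.head_activation == "sigmoid":
            r = _rescale(p, p0, u, u0, p0 * (1.0 - p0))
        else:
            r = np.ones_like(u)
        m_u = r / H  # (n,)
        mult[h + 1] += m_u[:, None] * net.head_w[h][None, :]

    # walk down through the nonlinearities and masked linear ops
    for l in range(H, 0, -1):
        if net.activations[l - 1] == "tanh":
            z, z0 = fwd["z"][l - 1], ref["z"][l - 1]
            a, a0 = fwd["a"][l], ref["a"][l]
            r = _rescale(a, a0, z, z0, 1.0 - a0**2)
        else:
            r = np.ones_like(fwd["z"][l - 1])
        m_z = mult[l] * r
        mult[l - 1] += m_z @ net.layers[l - 1].effective_weight.T

    sample_scores = [mult[l] * (fwd["a"][l] - ref["a"][l]) for l in range(n_act_layers)]

    # per-layer reachable target difference: heads h with h+1 >= l
    dp = fwd["p"] - ref["p"][:, 0][:, None]  # (H, n)
    delta_t = []
    for l in range(n_act_layers):
        lo = max(l - 1, 0)
        delta_t.append(dp[lo:].sum(axis=0) / H)

    node_names = degrees = None
    if model is not None and model.network is not None:
        from .hierarchy import degrees_by_layer

        node_names = [list(layer) for layer in model.network.layers]
        degrees = degrees_by_layer(model.network)

    return ImportanceScores(
        sample_scores=sample_scores,
        delta_t=delta_t,
        target=AttributionTarget(reference=x0[0], t=t, t0=t0),
        node_names=node_names,
        degrees=degrees,
    )


def aggregate_importance(sample_scores):
    """``C_i^l = |sum_s C_i^{l,s}|`` — absolute value of the signed sum."""
    s = np.atleast_2d(np.asarray(sample_scores, dtype=np.float64))
    if s.shape[0] < 1:
        raise ValueError("need at least one sample")
    return np.abs(s.sum(axis=0))


def adjust_importance(C, degrees):
    """Divide hub nodes' importance by their degree.

    A node is a hub when its degree exceeds the layer's mean degree plus
    five population standard deviations; all other scores are unchanged.
    The adjustment never increases a score (degrees that trigger it are
    necessarily > 1).
    """
    C = np.asarray(C, dtype=np.float64)
    d = np.asarray(degrees, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("degrees must be non-negative")
    if C.shape != d.shape:
        raise ValueError("importance and degree arrays must align")
    mu = d.mean()
    sigma = d.std()  # population formula
    hub = d > mu + 5.0 * sigma
    out = C.copy()
    out[hub] = C[hub] / d[hub]
    return out


@dataclass
class ActivationProfile:
    """Per-node activations split by class, with a two-sample statistic.

    ``statistic[l][i]`` is the Welch t statistic comparing node i's
    activation between class-1 and class-0 samples (positive when class 1
    activates higher); nodes with constant activation are flagged degenerate
    and given statistic 0.
    """

    activations: list  # per layer: (n_samples, n_l)
    statistic: list  # per layer: (n_l,)
    pvalue: list
    degenerate: list  # per layer: bool (n_l,)
    node_names: list | None = None

    def summary_frame(self, layer):
        rows = {
            "statistic": self.statistic[layer],
            "pvalue": self.pvalue[layer],
            "degenerate": self.degenerate[layer],
        }
        idx = self.node_names[layer] if self.node_names else None
        return pd.DataFrame(rows, index=idx)


def node_activation_analysis(fitted, X, y):
    """Welch t statistics of per-node activations between the two classes."""
    if isinstance(fitted, MaskedNet):
        net, model = fitted, None
    else:
        net, model = fitted.net, fitted.model
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("activation analysis needs both classes")
    acts = net.forward(X)["a"]
    stats_l, pvals_l, degen_l = [], [], []
    for a in acts:
        a1, a0 = a[y == 1], a[y == 0]
        const = (a.std(axis=0) == 0) | (a1.std(axis=0) == 0) & (a0.std(axis=0) == 0)
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # constant nodes trigger a scipy precision warning; they are
            # flagged degenerate below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a1, a0, axis=0, equal_var=False)
        t = np.where(np.isfinite(t), t, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        t[const] = 0.0
        p[const] = 1.0
        stats_l.append(t)
        pvals_l.append(p)
        degen_l.append(const)
    node_names = None
    if model is not None and model.network is not None:
        node_names = [list(layer) for layer in model.network.layers]
    return ActivationProfile(
        activations=acts,
        statistic=stats_l,
        pvalue=pvals_l,
        degenerate=degen_l,
        node_names=node_names,
    )


def export_importance_report(scores, net, outdir):
    """Write per-layer importance tables plus a Sankey-ready link table.

    One CSV per layer with columns ``node_id, display_name, layer, degree,
    C, adjusted_C, rank`` (rank 1 = highest adjusted importance, ties broken
    lexicographically by node id), and ``links.csv`` with each node's
    layer-normalised importance share split equally over its outgoing mask
    edges, so the shares out of a node sum to the node's own share.
    """
    from .hierarchy import degrees_by_layer

    if scores.sample_scores[0].shape[0] < 1:
        raise ValueError("cannot export a report from an empty evaluation set")
    os.makedirs(outdir, exist_ok=True)
    degs = degrees_by_layer(net)
    agg = scores.aggregate()
    adj = [adjust_importance(C, d) for C, d in zip(agg, degs)]

    for l, layer_nodes in enumerate(net.layers):
        order = sorted(range(len(layer_nodes)), key=lambda i: (-adj[l][i], layer_nodes[i]))
        rank = np.empty(len(layer_nodes), dtype=np.int64)
        rank[order] = np.arange(1, len(layer_nodes) + 1)
        pd.DataFrame(
            {
                "node_id": layer_nodes,
                "display_name": [net.display(x) for x in layer_nodes],
                "layer": l,
                "degree": degs[l],
                "C": agg[l],
                "adjusted_C": adj[l],
                "rank": rank,
            }
        ).to_csv(os.path.join(outdir, f"importance_layer{l}.csv"), index=False)

    links = []
    for l, m in enumerate(net.masks):
        total = adj[l].sum()
        share = adj[l] / total if total > 0 else np.zeros_like(adj[l])
        fan_out = m.sum(axis=1)
        for i, node in enumerate(net.layers[l]):
            if fan_out[i] == 0:
                continue
            per_edge = share[i] / fan_out[i]
            for j in np.flatnonzero(m[i]):
                links.append(
                    {
                        "source_node": node,
                        "target_node": net.layers[l + 1][j],
                        "share": per_edge,
                    }
                )
    pd.DataFrame(links).to_csv(os.path.join(outdir, "links.csv"), index=False)
    return outdir
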