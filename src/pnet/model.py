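"""Model-facing API: :class:`PNet` and :class:`PNetResults`.

Follows the familiar two-object pattern: a model is constructed from data
(a :class:`~pnet.genomics_io.ProfileTensor` or a flat feature matrix, the
binary disease-state labels, and a compiled
:class:`~pnet.hierarchy.LayeredNetwork`), ``fit()`` runs the optimiser and
returns a results object carrying the trained weights, the per-epoch
history, prediction and attribution methods and a ``summary()`` table.

A dense reference model — either with the same layer sizes or with the same
*parameter count* as the sparse model — is available through
:func:`dense_masks_like` and :func:`dense_matched_masks`; both are ordinary
:class:`PNet` models whose masks are all-ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import CohortLabels, ProfileTensor
from .hierarchy import LayeredNetwork, count_params
from .network import MaskedNet, TrainingConfig, average_heads

__all__ = [
    "PNet",
    "PNetResults",
    "PredictionOutput",
    "dense_masks_like",
    "dense_matched_masks",
    "ensemble_balanced_predict",
    "balanced_subsample",
]


@dataclass
class PredictionOutput:
    """Per-head probabilities and their mean (the final score)."""

    samples: list
    head_probs: np.ndarray  # (n_heads, n_samples)
    pnet_score: np.ndarray  # (n_samples,)

    def __post_init__(self):
        expect = average_heads(self.head_probs)
        if not np.allclose(self.pnet_score, expect):
            raise ValueError("pnet_score must be the mean of the head probabilities")


def _as_matrix_and_samples(X):
    if isinstance(X, ProfileTensor):
        return X.flatten(), list(X.samples)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return X, list(range(X.shape[0]))


def _as_labels(y, samples):
    if isinstance(y, CohortLabels):
        return y.vector(samples)
    return np.asarray(y, dtype=np.int64)


class PNet:
    """Pathway-constrained sparse classifier of tumour disease state.

    Parameters
    ----------
    profiles : ProfileTensor or array (n_samples, n_features)
        Per-gene mutation / amplification / deletion channels, flattened in
        the network's feature-node order.
    labels : CohortLabels or array of {0, 1}
        0 = primary, 1 = metastatic / castration-resistant.
    network : LayeredNetwork or list of masks
        The compiled topology.  Passing a plain list of binary matrices
        builds an unconstrained (dense) model with those shapes.
    config : TrainingConfig, optional

    Examples
    --------
    >>> model = PNet(tensor, labels, net)            # doctest: +SKIP
    >>> res = model.fit(seed=7)                      # doctest: +SKIP
    >>> res.predict(tensor).pnet_score               # doctest: +SKIP
    """

    def __init__(self, profiles, labels, network, config=None):
        self.X, self.samples = _as_matrix_and_samples(profiles)
        self.y = _as_labels(labels, self.samples)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("profiles and labels disagree on sample count")
        if isinstance(network, LayeredNetwork):
            self.network = network
            self.masks = [m.astype(np.float64) for m in network.masks]
        else:
            self.network = None
            self.masks = [np.asarray(m, dtype=np.float64) for m in network]
        if self.X.shape[1] != self.masks[0].shape[0]:
            raise ValueError(
                f"feature count {self.X.shape[1]} does not match first mask "
                f"fan-in {self.masks[0].shape[0]}"
            )
        self.config = config or TrainingConfig()

    @classmethod
    def from_cohort(cls, cohort, config=None, n_pathway_layers=None):
        """Build model and topology directly from a synthetic cohort."""
        from .hierarchy import build_layered_network

        K = n_pathway_layers or len(cohort.config.layer_widths)
        net = build_layered_network(cohort.graph, cohort.genesets, n_pathway_layers=K)
        tensor = cohort.tensor
        if tensor.genes != net.genes:
            raise ValueError("cohort tensor gene order does not match compiled network")
        return cls(tensor, cohort.labels, net, config=config)

    @property
    def param_count(self):
        if self.network is not None:
            return count_params(self.network)
        n_sparse = sum(int(m.sum()) + m.shape[1] for m in self.masks)
        n_sparse += sum(m.shape[1] + 1 for m in self.masks)
        return n_sparse

    def fit(self, seed=None, validation=None, epochs=None):
        """Train and return a :class:`PNetResults`.

        Parameters
        ----------
        seed : int, optional
            Overrides ``config.seed`` for both initialisation and batching.
        validation : tuple (X, y), optional
            Held-out set; when given, the epoch with the best validation AUC
            is restored at the end of training.
        epochs : int, optional
            Override ``config.epochs``.
        """
        cfg = self.config
        if seed is not None or epochs is not None:
            kw = {k: getattr(cfg, k) for k in TrainingConfig.__dataclass_fields__}
            if seed is not None:
                kw["seed"] = int(seed)
            if epochs is not None:
                kw["epochs"] = int(epochs)
            cfg = TrainingConfig(**kw)
        net = MaskedNet(self.masks, seed=cfg.seed)
        if validation is not None:
            Xv, _ = _as_matrix_and_samples(validation[0])
            yv = _as_labels(validation[1], None)
            validation = (Xv, yv)
        history = net.fit(self.X, self.y, cfg, validation=validation)
        return PNetResults(model=self, net=net, config=cfg, history=history)


class PNetResults:
    """Fitted model: weights, history, prediction, attribution, summary."""

    def __init__(self, model, net, config, history):
        self.model = model
        self.net = net
        self.config = config
        self._history = history

    @property
    def history(self):
        """Per-epoch loss / learning rate / validation AUC as a DataFrame."""
        return pd.DataFrame(self._history)

    @property
    def params(self):
        return self.net.get_params()

    def predict(self, X=None):
        """Score samples; defaults to the training profiles."""
        if X is None:
            Xm, samples = self.model.X, self.model.samples
        else:
            Xm, samples = _as_matrix_and_samples(X)
        p = self.net.predict_heads(Xm)
        return PredictionOutput(samples=samples, head_probs=p, pnet_score=average_heads(p))

    def explain(self, X=None, reference=None, sample_set=None):
        """DeepLIFT rescale importance scores; see :mod:`pnet.attribution`."""
        from .attribution import deeplift_scores

        if X is None:
            X = self.model.X
        Xm, _ = _as_matrix_and_samples(X)
        if sample_set is not None:
            Xm = Xm[np.asarray(sample_set)]
        return deeplift_scores(self, Xm, reference=reference)

    def summary(self):
        """Plain-text fit summary (architecture, parameters, final metrics)."""
        n_l = [m.shape[0] for m in self.model.masks] + [self.model.masks[-1].shape[1]]
        sparse = sum(int(m.sum()) + m.shape[1] + m.shape[1] + 1 for m in self.model.masks)
        dense = sum(
            m.shape[1] * (m.shape[0] + 1) + m.shape[1] + 1 for m in self.model.masks
        )
        lines = [
            "P-NET results",
            "=" * 46,
            f"layers (nodes):        {' -> '.join(str(k) for k in n_l)}",
            f"trainable parameters:  {sparse}",
            f"dense equivalent:      {dense}",
            f"heads:                 {self.net.n_heads}",
            f"epochs trained:        {len(self._history)}",
        ]
        if self._history:
            lines.append(f"final training loss:   {self._history[-1]['loss']:.4f}")
            if "val_auc" in self._history[-1]:
                best = max(h["val_auc"] for h in self._history if "val_auc" in h)
                lines.append(f"best validation AUC:   {best:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, path):
        """Write a self-describing HDF5 checkpoint (masks, weights, nodes)."""
        save_checkpoint(self, path)


# ---------------------------------------------------------------------------
# dense references


def dense_masks_like(network):
    """All-ones masks with the same layer sizes as *network* (dense twin)."""
    masks = network.masks if isinstance(network, LayeredNetwork) else network
    return [np.ones_like(np.asarray(m, dtype=np.float64)) for m in masks]


def dense_matched_masks(n_features, target_params, n_hidden=1):
    """Dense architecture with approximately *target_params* parameters.

    Solves for a uniform hidden width h such that the fully connected
    network ``n_features -> h (x n_hidden) -> 1`` with per-layer heads has a
    parameter count as close as possible to the target (at least width 1).
    This is the "same number of parameters" comparison model for learning
    curves: with a wide input, matching a sparse budget forces the dense
    model to be very narrow.
    """

    def n_params(h):
        widths = [n_features] + [h] * n_hidden + [1]
        total = 0
        for l in range(1, len(widths)):
            total += widths[l] * (widths[l - 1] + 1)  # dense weights + bias
            total += widths[l] + 1  # head
        return total

    h = 1
    while n_params(h + 1) <= target_params:
        h += 1
    if abs(n_params(h + 1) - target_params) < abs(n_params(h) - target_params):
        h += 1
    widths = [n_features] + [h] * n_hidden + [1]
    return [np.ones((widths[l - 1], widths[l])) for l in range(1, len(widths))]


# ---------------------------------------------------------------------------
# balanced-subsample ensemble


def balanced_subsample(y, n_members, seed):
    """Index sets: all minority samples + an equal-size majority draw each.

    Majority draws are disjoint across members as long as the majority class
    is large enough, then wrap around (reshuffled).  Deterministic given the
    seed.
    """
    y = np.asarray(y)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    minority, majority = (idx1, idx0) if len(idx1) <= len(idx0) else (idx0, idx1)
    if len(minority) < 2:
        raise ValueError("minority class must have at least 2 samples")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(majority)
    members = []
    pos = 0
    k = len(minority)
    for _ in range(n_members):
        if pos + k > len(pool):
            pool = rng.permutation(majority)
            pos = 0
        draw = pool[pos : pos + k]
        pos += k
        members.append(np.sort(np.concatenate([minority, draw])))
    return members


def ensemble_balanced_predict(
    profiles, labels, network, config=None, X_eval=None, n_members=2, seed=0
):
    """Average the scores of models trained on balanced subsamples.

    Mirrors the external-validation protocol: each member sees all minority
    samples plus an equally sized majority draw; the prediction for new data
    is the mean of the member scores.

    Returns
    -------
    (scores, members) : (ndarray, list of PNetResults)
    """
    X, samples = _as_matrix_and_samples(profiles)
    y = _as_labels(labels, samples)
    if X_eval is None:
        X_eval = X
    else:
        X_eval, _ = _as_matrix_and_samples(X_eval)
    subsets = balanced_subsample(y, n_members, seed)
    members = []
    scores = np.zeros(X_eval.shape[0])
    for m, idx in enumerate(subsets):
        res = PNet(X[idx], y[idx], network, config=config).fit(seed=seed + m)
        members.append(res)
        scores += res.predict(X_eval).pnet_score
    return scores / n_members, members


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(results, path):
    import h5py
    import yaml

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "pnet-checkpoint-v1"
        cfg = {k: getattr(results.config, k) for k in TrainingConfig.__dataclass_fields__}
        if cfg["head_loss_weights"] is not None:
            cfg["head_loss_weights"] = list(cfg["head_loss_weights"])
        f.attrs["config"] = yaml.safe_dump(cfg)
        for l, layer in enumerate(results.net.layers):
            g = f.create_group(f"layer{l}")
            g.create_dataset("M", data=layer.M)
            g.create_dataset("W", data=layer.W)
            g.create_dataset("b", data=layer.b)
            g.create_dataset("head_w", data=results.net.head_w[l])
            g.attrs["head_b"] = results.net.head_b[l]
        if results.model.network is not None:
            nodes = f.create_group("nodes")
            for l, layer_nodes in enumerate(results.model.network.layers):
                nodes.create_dataset(
                    f"layer{l}", data=np.array(layer_nodes, dtype=h5py.string_dtype())
                )


def load_checkpoint(path):
    """Rebuild a :class:`MaskedNet` (and node lists, if stored) from HDF5."""
    import h5py
    import yaml

    with h5py.File(path, "r") as f:
        cfg = TrainingConfig(**yaml.safe_load(f.attrs["config"]))
        masks, params = [], {"W": [], "b": [], "head_w": [], "head_b": []}
        l = 0
        while f"layer{l}" in f:
            g = f[f"layer{l}"]
            masks.append(g["M"][...])
            params["W"].append(g["W"][...])
            params["b"].append(g["b"][...])
            params["head_w"].append(g["head_w"][...])
            params["head_b"].append(float(g.attrs["head_b"]))
            l += 1
        node_layers = None
        if "nodes" in f:
            node_layers = []
            k = 0
            while f"layer{k}" in f["nodes"]:
                node_layers.append([s.decode() for s in f["nodes"][f"layer{k}"][...]])
                k += 1
    net = MaskedNet(masks, seed=cfg.seed)
    net.set_params(params)
    return net, node_layers, cfg
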