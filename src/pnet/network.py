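"""NumPy core of the masked feed-forward network.

Each hidden layer computes ``a_l = tanh((M_l * W_l)^T a_{l-1} + b_l)`` where
``M_l`` is a fixed binary mask and ``*`` the Hadamard product, so a weight
only exists where the compiled topology has an edge.  Every hidden layer
additionally feeds a one-unit sigmoid prediction head; the network's final
score is the arithmetic mean of the head probabilities.  Training minimises
a head-weighted, class-weighted binary cross-entropy with Adam and a stepped
learning-rate schedule.

Everything here is dense NumPy with explicit gradients: masking a gradient
is the same elementwise product as masking the weight, which keeps the
"masked-out weights never matter" contract exact, and a hand-rolled forward
pass is what the DeepLIFT rescale backward pass in :mod:`pnet.attribution`
walks through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskedLayer",
    "TrainingConfig",
    "MaskedNet",
    "masked_forward",
    "head_predict",
    "average_heads",
    "weighted_bce",
    "class_weights",
    "sigmoid",
]

EPS_CLIP = 1e-7


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MaskedLayer:
    """One masked linear layer with tanh activation.

    ``M`` is immutable after construction (enforced via a read-only view);
    the effective weight is the elementwise product ``M * W``.
    """

    M: np.ndarray
    W: np.ndarray
    b: np.ndarray
    activation: str = "tanh"

    def __post_init__(self):
        M = np.ascontiguousarray(np.asarray(self.M, dtype=np.float64))
        M.setflags(write=False)
        object.__setattr__(self, "M", M)
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.M.shape != self.W.shape:
            raise ValueError(f"mask shape {self.M.shape} != weight shape {self.W.shape}")
        if self.b.shape != (self.M.shape[1],):
            raise ValueError("bias length must equal layer width")

    @property
    def effective_weight(self):
        return self.M * self.W

    def pre_activation(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.M.shape[0]:
            raise ValueError(
                f"input width {x.shape[-1]} does not match layer fan-in {self.M.shape[0]}"
            )
        return x @ self.effective_weight + self.b


def masked_forward(x, layer):
    """``y = tanh((M * W)^T x + b)``; weights where M == 0 have no effect."""
    return np.tanh(layer.pre_activation(x))


def head_predict(h, head_w, head_b=0.0):
    """Sigmoid prediction head: probability in (0, 1)."""
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    return sigmoid(h @ np.asarray(head_w, dtype=np.float64) + head_b)


def average_heads(head_probs):
    """Final score: arithmetic mean of the per-layer head probabilities."""
    head_probs = np.asarray(head_probs, dtype=np.float64)
    if head_probs.shape[0] < 1:
        raise ValueError("need at least one head")
    return head_probs.mean(axis=0)


def class_weights(train_labels):
    """Balanced inverse-frequency weights ``w_c = N / (2 n_c)``.

    Raises if a class is absent: the loss needs both classes represented.
    """
    y = np.asarray(train_labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("class weighting requires both classes in the training set")
    N = len(y)
    return {0: N / (2.0 * n0), 1: N / (2.0 * n1)}


def weighted_bce(y, head_probs, class_weight=None, head_loss_weights=None):
    """Total loss: sum over heads of head_weight x class-weighted BCE.

    ``head_probs`` has shape (n_heads, n_samples); probabilities are clipped
    to [eps, 1-eps] with eps = 1e-7 before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    P = np.atleast_2d(np.asarray(head_probs, dtype=np.float64))
    n_heads, n = P.shape
    if head_loss_weights is None:
        head_loss_weights = np.ones(n_heads)
    hw = np.asarray(head_loss_weights, dtype=np.float64)
    if class_weight is None:
        sw = np.ones(n)
    else:
        sw = np.where(y == 1, class_weight[1], class_weight[0])
    P = np.clip(P, EPS_CLIP, 1.0 - EPS_CLIP)
    per_head = -(sw * (y * np.log(P) + (1.0 - y) * np.log(1.0 - P))).mean(axis=1)
    return float(hw @ per_head)


@dataclass
class TrainingConfig:
    """Optimisation hyperparameters.

    The learning rate starts at ``lr_init`` and is multiplied by
    ``lr_drop_factor`` after every ``lr_drop_every`` epochs.  Head loss
    weights default to a geometric ramp doubling per layer (later, narrower
    layers are harder to fit and get more weight); ``class_weight_mode``
    "balanced" applies ``w_c = N / (2 n_c)`` from the training labels.
    """

    lr_init: float = 1e-3
    lr_drop_every: int = 50
    lr_drop_factor: float = 0.5
    epochs: int = 300
    batch_size: int = 50
    class_weight_mode: str = "balanced"  # or "none"
    head_loss_weights: tuple | None = None  # default: geometric ramp 1,2,4,...
    l2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lr_drop_factor < 1.0):
            raise ValueError("lr_drop_factor must be in (0, 1)")
        for name in ("lr_init", "lr_drop_every", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")

    def lr_at(self, epoch):
        return self.lr_init * self.lr_drop_factor ** (epoch // self.lr_drop_every)

    def resolve_head_weights(self, n_heads):
        if self.head_loss_weights is not None:
            hw = np.asarray(self.head_loss_weights, dtype=np.float64)
            if len(hw) != n_heads:
                raise ValueError(f"expected {n_heads} head loss weights, got {len(hw)}")
            if np.any(np.diff(hw) < 0):
                raise ValueError("head loss weights must be non-decreasing")
            return hw
        return 2.0 ** np.arange(n_heads)


def _auc(y, s):
    """Rank-statistic AUC with tie correction (Mann-Whitney)."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=np.float64)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return np.nan
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=np.float64)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)


class MaskedNet:
    """A stack of :class:`MaskedLayer` with a sigmoid head per hidden layer.

    Parameters
    ----------
    masks : list of 2-D arrays
        Binary connectivity, ``masks[l]`` of shape (n_l, n_{l+1}); an
        all-ones mask gives an ordinary dense layer.
    seed : int
        Seeds the Glorot-uniform initialisation (full layer shape; masked-out
        entries are zeroed and never updated).
    """

    #: mask density below which a layer trains on compressed (nonzero-only)
    #: weight vectors with sparse matmuls instead of dense arrays
    SPARSE_DENSITY = 0.25

    def __init__(self, masks, seed=0, activations=None, head_activation="sigmoid"):
        rng = np.random.default_rng(seed)
        if activations is None:
            activations = ["tanh"] * len(masks)
        if len(activations) != len(masks):
            raise ValueError("need one activation per layer")
        if any(a not in ("tanh", "identity") for a in activations):
            raise ValueError("activations must be 'tanh' or 'identity'")
        if head_activation not in ("sigmoid", "identity"):
            raise ValueError("head_activation must be 'sigmoid' or 'identity'")
        self.activations = list(activations)
        self.head_activation = head_activation
        self.layers = []
        self._patterns = []  # (rows, cols) of mask nonzeros, or None for dense
        for M in masks:
            M = np.asarray(M, dtype=np.float64)
            # Glorot-uniform on the full layer shape.  Scaling by the sparse
            # (mask) fan-in instead makes the initial weights ~O(1): the tanh
            # units then start as a high-variance random feature map that
            # memorises small training sets and destroys the sparse model's
            # small-sample advantage.  Small initial weights keep the network
            # near-linear at the start, and the curated masks do the rest.
            limit = np.sqrt(6.0 / (M.shape[0] + M.shape[1]))
            W = rng.uniform(-limit, limit, size=M.shape) * M
            self.layers.append(MaskedLayer(M=M, W=W, b=np.zeros(M.shape[1])))
            density = M.sum() / M.size
            if density <= self.SPARSE_DENSITY and M.size > 1024:
                r, c = np.nonzero(M)
                self._patterns.append((r, c))
            else:
                self._patterns.append(None)
        self.head_w = []
        self.head_b = []
        for M in masks:
            n = M.shape[1]
            lim = np.sqrt(6.0 / (n + 1.0))
            self.head_w.append(rng.uniform(-lim, lim, size=n))
            self.head_b.append(0.0)
        self.n_heads = len(self.layers)

    def _op(self, l):
        """Effective-weight operator for layer l (sparse where profitable)."""
        layer = self.layers[l]
        pat = self._patterns[l]
        if pat is None:
            return layer.effective_weight
        r, c = pat
        from scipy import sparse as sp

        return sp.csr_matrix((layer.W[r, c], (r, c)), shape=layer.W.shape)

    # -- forward ----------------------------------------------------------

    def forward(self, X):
        """Full forward pass; returns activations, pre-activations and heads."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.layers[0].M.shape[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match network fan-in "
                f"{self.layers[0].M.shape[0]}"
            )
        a = [X]
        z = []
        self._ops = [self._op(l) for l in range(len(self.layers))]
        for layer, op, act in zip(self.layers, self._ops, self.activations):
            z.append(np.asarray(a[-1] @ op) + layer.b)
            a.append(np.tanh(z[-1]) if act == "tanh" else z[-1])
        u = [a[l + 1] @ self.head_w[l] + self.head_b[l] for l in range(self.n_heads)]
        if self.head_activation == "sigmoid":
            p = np.stack([sigmoid(ui) for ui in u])  # (n_heads, n_samples)
        else:
            p = np.stack(u)
        return {"a": a, "z": z, "u": u, "p": p, "score": average_heads(p)}

    def predict(self, X):
        """P-NET score: mean of head probabilities, in [0, 1]."""
        return self.forward(X)["score"]

    def predict_heads(self, X):
        return self.forward(X)["p"]

    # -- parameters -------------------------------------------------------

    def get_params(self):
        return {
            "W": [l.W.copy() for l in self.layers],
            "b": [l.b.copy() for l in self.layers],
            "head_w": [w.copy() for w in self.head_w],
            "head_b": list(self.head_b),
        }

    def set_params(self, params):
        for l, W, b in zip(self.layers, params["W"], params["b"]):
            l.W = W.copy()
            l.b = b.copy()
        self.head_w = [w.copy() for w in params["head_w"]]
        self.head_b = list(params["head_b"])

    # -- gradients --------------------------------------------------------

    def _backward(self, cache, y, sample_weight, head_loss_weights, l2):
        """Gradients of the total loss for one batch.

        For a sigmoid head with BCE the pre-activation gradient is
        ``(p - y)``; multipliers flow down through the tanh layers with the
        masked effective weights, and every weight gradient is re-masked so
        masked-out entries never receive updates.
        """
        a, z, p = cache["a"], cache["z"], cache["p"]
        n = len(y)
        yf = np.asarray(y, dtype=np.float64)
        gW = [None] * len(self.layers)  # dense array, or compressed nnz vector
        gb = [np.zeros_like(l.b) for l in self.layers]
        ghw = [np.zeros_like(w) for w in self.head_w]
        ghb = [0.0] * self.n_heads

        d_a = [np.zeros_like(ai) for ai in a]  # gradient wrt activations
        for h in range(self.n_heads):
            du = head_loss_weights[h] * sample_weight * (p[h] - yf) / n  # (n,)
            ghw[h] = a[h + 1].T @ du
            ghb[h] = float(du.sum())
            d_a[h + 1] += du[:, None] * self.head_w[h][None, :]

        for l in range(self.n_heads - 1, -1, -1):
            if self.activations[l] == "tanh":
                dz = d_a[l + 1] * (1.0 - a[l + 1] ** 2)  # tanh'
            else:
                dz = d_a[l + 1]
            layer = self.layers[l]
            pat = self._patterns[l]
            if pat is None:
                gW[l] = layer.M * (a[l].T @ dz)
                if l2 > 0:
                    gW[l] += l2 * layer.M * layer.W
            else:
                r, c = pat
                gW[l] = np.einsum("ij,ij->j", a[l][:, r], dz[:, c])
                if l2 > 0:
                    gW[l] += l2 * layer.W[r, c]
            gb[l] = dz.sum(axis=0)
            d_a[l] += np.asarray(dz @ self._ops[l].T)

        return gW, gb, ghw, ghb

    def loss(self, X, y, class_weight=None, head_loss_weights=None):
        p = self.forward(X)["p"]
        return weighted_bce(y, p, class_weight, head_loss_weights)

    # -- training ---------------------------------------------------------

    def fit(self, X, y, config, validation=None):
        """Train with Adam + stepped learning rate; returns per-epoch history.

        With a ``validation=(Xv, yv)`` pair the weights with the best
        validation AUC are restored at the end (ties keep the earlier
        epoch).  Deterministic given ``config.seed``.
        """
        if self.head_activation != "sigmoid":
            raise ValueError("training requires sigmoid heads (BCE loss)")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        hw = config.resolve_head_weights(self.n_heads)
        if config.class_weight_mode == "balanced":
            cw = class_weights(y)
        else:
            cw = {0: 1.0, 1: 1.0}
        sw_all = np.where(y == 1, cw[1], cw[0]).astype(np.float64)

        rng = np.random.default_rng(config.seed)
        # sparse layers train on compressed nonzero-only weight vectors,
        # scattered back into the dense W after every update
        params = []
        for l, layer in enumerate(self.layers):
            if self._patterns[l] is None:
                params.append(layer.W)
            else:
                r, c = self._patterns[l]
                params.append(layer.W[r, c])
        params += [layer.b for layer in self.layers] + list(self.head_w)
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        hb_m = [0.0] * self.n_heads
        hb_v = [0.0] * self.n_heads
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        history = []
        best = None  # (val_auc, epoch, params)
        n = len(y)
        for epoch in range(config.epochs):
            lr = config.lr_at(epoch)
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                cache = self.forward(X[idx])
                gW, gb, ghw, ghb = self._backward(cache, y[idx], sw_all[idx], hw, config.l2)
                grads = gW + gb + ghw
                t += 1
                corr1 = 1.0 - beta1**t
                corr2 = 1.0 - beta2**t
                for k, (p_arr, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    p_arr -= lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + eps)
                for l, layer in enumerate(self.layers):
                    if self._patterns[l] is not None:
                        r, c = self._patterns[l]
                        layer.W[r, c] = params[l]
                for h in range(self.n_heads):
                    hb_m[h] = beta1 * hb_m[h] + (1 - beta1) * ghb[h]
                    hb_v[h] = beta2 * hb_v[h] + (1 - beta2) * ghb[h] ** 2
                    self.head_b[h] -= lr * (hb_m[h] / corr1) / (
                        np.sqrt(hb_v[h] / corr2) + eps
                    )

            ep_loss = self.loss(X, y, cw, hw)
            if not np.isfinite(ep_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {ep_loss!r}; "
                    "check input scaling and learning rate"
                )
            rec = {"epoch": epoch, "lr": lr, "loss": ep_loss}
            if validation is not None:
                Xv, yv = validation
                val_auc = _auc(yv, self.predict(Xv))
                rec["val_auc"] = val_auc
                if np.isfinite(val_auc) and (best is None or val_auc > best[0]):
                    best = (val_auc, epoch, self.get_params())
            history.append(rec)

        if best is not None:
            self.set_params(best[2])
        return history
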