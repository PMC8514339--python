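"""Splits, cross-validation, metrics, baselines and statistical tests.

Implements the full evaluation protocol around the model: stratified
80/10/10 splits, stratified five-fold CV, threshold and ranking metrics,
the paired DeLong test for AUC differences, a bootstrap median-difference
test for the other metrics, Benjamini-Hochberg FDR correction, the
sparse-versus-dense learning-curve experiment, conventional baseline
classifiers, and the Yates-corrected chi-squared and log-rank tests used
for the clinical follow-up analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SplitSpec",
    "MetricSet",
    "ComparisonResult",
    "LearningCurveResult",
    "make_splits",
    "make_cv_folds",
    "compute_metrics",
    "delong_test",
    "bootstrap_median_test",
    "fdr_adjust",
    "learning_curve",
    "baselines",
    "chi2_yates",
    "logrank_test",
]


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    """Index partition into train / validation / test, plus optional CV folds.

    The validation set has the same size as the test set; all three are
    disjoint and exhaustive.  ``cv_folds`` (when attached) partitions the
    development set (train + validation).
    """

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    cv_folds: list = field(default_factory=list)

    def __post_init__(self):
        parts = [set(self.train), set(self.validation), set(self.test)]
        n = sum(len(p) for p in parts)
        if len(set().union(*parts)) != n:
            raise ValueError("split parts overlap")
        if len(self.validation) != len(self.test):
            raise ValueError("validation size must equal test size")

    @property
    def dev(self):
        """Development set = train + validation, sorted."""
        return np.sort(np.concatenate([self.train, self.validation]))


def make_splits(labels, test_frac=0.10, seed=0):
    """Stratified 80/10/10 split (train / validation / test).

    The test set takes ``ceil(n * test_frac)`` samples (stratified); the
    validation set is drawn from the remainder with exactly the same size.
    Deterministic given the seed.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 10:
        raise ValueError("need at least 10 samples per class to split 80/10/10")
    idx = np.arange(len(y))
    n_test = int(np.ceil(len(y) * test_frac))
    dev_idx, test_idx = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed
    )
    train_idx, val_idx = train_test_split(
        dev_idx, test_size=n_test, stratify=y[dev_idx], random_state=seed
    )
    return SplitSpec(
        train=np.sort(train_idx),
        validation=np.sort(val_idx),
        test=np.sort(test_idx),
        seed=seed,
    )


def make_cv_folds(dev_labels, k=5, seed=0):
    """Stratified, disjoint, exhaustive k-fold partition of the dev set."""
    y = np.asarray(dev_labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(np.sort(tr), np.sort(te)) for tr, te in skf.split(np.zeros(len(y)), y)]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricSet:
    """Standard binary-classification metrics on one evaluation set.

    ``auc``/``auprc`` are NaN (and listed in ``notes``) when only one class
    is present; an undefined precision (no positive predictions) is reported
    as 0 with ``precision_undefined`` set.
    """

    auc: float
    auprc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    precision_undefined: bool = False
    notes: tuple = ()

    def as_dict(self):
        return {
            "auc": self.auc,
            "auprc": self.auprc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
        }


def compute_metrics(y, scores, threshold=0.5):
    """AUC (rank statistic, tie-corrected), AUPRC (step-interpolated) and
    threshold metrics at the stated cutoff."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=np.float64)
    notes = []
    if len(np.unique(y)) < 2:
        auc = auprc = np.nan
        notes.append("single-class evaluation set: AUC/AUPRC undefined")
    else:
        auc = roc_auc_score(y, s)
        auprc = average_precision_score(y, s)
    pred = (s >= threshold).astype(int)
    prec_undef = pred.sum() == 0
    return MetricSet(
        auc=float(auc),
        auprc=float(auprc),
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred, zero_division=0)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        precision_undefined=bool(prec_undef),
        notes=tuple(notes),
    )


# Plain-NumPy metric implementations for the resampling loops (identical
# semantics to the scikit-learn calls in compute_metrics, ~100x less call
# overhead; equality is asserted in the test suite).


def _fast_auc(y, s):
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        return np.nan
    r = _midrank(np.asarray(s, dtype=np.float64))
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def _fast_auprc(y, s):
    """Step-interpolated average precision with tie grouping."""
    y = np.asarray(y)
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        return np.nan
    order = np.argsort(-np.asarray(s, dtype=np.float64), kind="mergesort")
    ys = y[order]
    ss = np.asarray(s, dtype=np.float64)[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    last = np.r_[ss[1:] != ss[:-1], True]  # group boundaries of tied scores
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n1
    d_recall = np.diff(np.r_[0.0, recall])
    return float((d_recall * precision).sum())


def _thresholded(y, s):
    pred = (np.asarray(s, dtype=np.float64) >= 0.5).astype(int)
    y = np.asarray(y)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return pred, tp, fp, fn


def _fast_f1(y, s):
    _, tp, fp, fn = _thresholded(y, s)
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


_METRIC_FNS = {
    "auc": _fast_auc,
    "auprc": _fast_auprc,
    "accuracy": lambda y, s: float((_thresholded(y, s)[0] == np.asarray(y)).mean()),
    "f1": _fast_f1,
    "precision": lambda y, s: (lambda t: t[1] / (t[1] + t[2]) if (t[1] + t[2]) else 0.0)(
        _thresholded(y, s)
    ),
    "recall": lambda y, s: (lambda t: t[1] / (t[1] + t[3]) if (t[1] + t[3]) else 0.0)(
        _thresholded(y, s)
    ),
}


# ---------------------------------------------------------------------------
# statistical tests


@dataclass
class ComparisonResult:
    """One model-vs-model metric comparison."""

    metric: str
    statistic: float
    pvalue: float
    pvalue_adjusted: float | None
    method: str


def _midrank(x):
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=np.float64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.empty(n, dtype=np.float64)
    out[order] = ranks
    return out


def delong_test(y, scores_a, scores_b):
    """Paired DeLong test for the difference of two correlated ROC AUCs.

    Returns ``(auc_a, auc_b, pvalue)``; the two-sided p-value comes from the
    normal approximation with the DeLong covariance of the paired AUC
    estimates.  Identical score vectors (zero variance of the difference)
    give p = 1.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("DeLong test needs both classes")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m, n = len(pos), len(neg)
    aucs = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, s in enumerate((np.asarray(scores_a, float), np.asarray(scores_b, float))):
        all_r = _midrank(np.concatenate([s[pos], s[neg]]))
        pos_r = _midrank(s[pos])
        neg_r = _midrank(s[neg])
        auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs.append(auc)
        v10[k] = (all_r[:m] - pos_r) / n
        v01[k] = 1.0 - (all_r[m:] - neg_r) / m
    s10 = np.cov(v10) / m
    s01 = np.cov(v01) / n
    cov = s10 + s01
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var_diff <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(min(p, 1.0))


def bootstrap_median_test(y, scores_a, scores_b, metric="auprc", n_boot=2000, seed=0):
    """Bootstrap test of the median metric difference between two models.

    Test indices are resampled with replacement ``n_boot`` times; each
    resample yields the metric for both models and their difference.  The
    two-sided p-value doubles the smaller tail of the bootstrap difference
    distribution around zero, with add-one smoothing: ``2 * min((#{d<=0}+1),
    (#{d>=0}+1)) / (n_valid + 1)``, capped at 1.  Resamples on which the
    metric is undefined (single-class draws) are discarded from the counts.
    """
    y = np.asarray(y)
    sa = np.asarray(scores_a, dtype=np.float64)
    sb = np.asarray(scores_b, dtype=np.float64)
    fn = _METRIC_FNS[metric] if isinstance(metric, str) else metric
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(y)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        da = fn(y[idx], sa[idx])
        db = fn(y[idx], sb[idx])
        if np.isfinite(da) and np.isfinite(db):
            diffs.append(da - db)
    diffs = np.asarray(diffs)
    if len(diffs) == 0 or np.median(diffs) == 0 and np.all(diffs == 0):
        return 1.0
    b = len(diffs)
    c_le = (np.sum(diffs <= 0) + 1) / (b + 1)
    c_ge = (np.sum(diffs >= 0) + 1) / (b + 1)
    return float(min(1.0, 2.0 * min(c_le, c_ge)))


def fdr_adjust(pvals):
    """Benjamini-Hochberg step-up adjustment (monotone)."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_models(y, scores_a, scores_b, metrics=("auc", "auprc", "accuracy", "f1", "recall"), n_boot=2000, seed=0):
    """AUC via DeLong, other metrics via bootstrap; FDR-adjust jointly."""
    results = []
    for m in metrics:
        if m == "auc":
            _, _, p = delong_test(y, scores_a, scores_b)
            stat = _METRIC_FNS["auc"](y, scores_a) - _METRIC_FNS["auc"](y, scores_b)
            results.append(ComparisonResult(m, float(stat), p, None, "delong"))
        else:
            p = bootstrap_median_test(y, scores_a, scores_b, metric=m, n_boot=n_boot, seed=seed)
            stat = _METRIC_FNS[m](y, scores_a) - _METRIC_FNS[m](y, scores_b)
            results.append(ComparisonResult(m, float(stat), p, None, "bootstrap_median"))
    adj = fdr_adjust([r.pvalue for r in results])
    return [
        ComparisonResult(r.metric, r.statistic, r.pvalue, float(a), r.method)
        for r, a in zip(results, adj)
    ]


# ---------------------------------------------------------------------------
# learning curve


@dataclass
class LearningCurveResult:
    """Fold-level scores per (model, size, seed) plus per-size comparisons."""

    records: pd.DataFrame  # columns: model, size, seed, fold, metric, value

    def summary(self, metric="auc"):
        df = self.records[self.records["metric"] == metric]
        return (
            df.groupby(["model", "size"])["value"]
            .agg(["mean", "std"])
            .reset_index()
            .sort_values(["model", "size"])
        )

    def t_test(self, model_a, model_b, metric="auc"):
        """Per-size equal-variance t-test of mean fold scores (two-sided)."""
        df = self.records[self.records["metric"] == metric]
        rows = []
        for size, grp in df.groupby("size"):
            a = grp[grp["model"] == model_a]["value"].to_numpy()
            b = grp[grp["model"] == model_b]["value"].to_numpy()
            if np.var(a) == 0 and np.var(b) == 0:
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
                t = 0.0 if np.mean(a) == np.mean(b) else np.inf
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append({"size": size, "statistic": float(t), "pvalue": float(p)})
        return pd.DataFrame(rows).sort_values("size").reset_index(drop=True)


def default_sizes(n_dev, n_points=6, start=100):
    """Log-spaced training-set sizes from *start* to the dev-set size."""
    if n_dev < start:
        raise ValueError("dev set smaller than the smallest size")
    return sorted(set(np.unique(np.geomspace(start, n_dev, n_points).astype(int))))


def learning_curve(X, y, model_builders, sizes=None, k=5, seeds=(0, 1, 2, 3, 4), metrics=("auc",)):
    """Sparse-vs-dense style experiment over increasing training-set sizes.

    Parameters
    ----------
    X, y : arrays
        Development data (the experiment subsamples from these).
    model_builders : dict name -> callable(X_tr, y_tr, X_te, seed) -> scores
        Each builder trains its model and returns scores on ``X_te``.
    sizes : list of int, optional
        Defaults to 6 log-spaced points from 100 to ``len(y)``.
    k : int
        CV folds per size.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if sizes is None:
        sizes = default_sizes(len(y))
    sizes = sorted(sizes)
    if max(sizes) > len(y):
        raise ValueError("requested size exceeds the dev set")
    if min(sizes) < 2 * k:
        raise ValueError(f"smallest size must be at least 2k = {2 * k}")
    records = []
    for seed in seeds:
        for size in sizes:
            if size < len(y):
                sub, _ = train_test_split(
                    np.arange(len(y)), train_size=size, stratify=y, random_state=seed
                )
            else:
                sub = np.arange(len(y))
            Xs, ys = X[sub], y[sub]
            folds = make_cv_folds(ys, k=k, seed=seed)
            for fold_id, (tr, te) in enumerate(folds):
                for name, build in model_builders.items():
                    scores = build(Xs[tr], ys[tr], Xs[te], seed)
                    ms = compute_metrics(ys[te], scores)
                    for metric in metrics:
                        records.append(
                            {
                                "model": name,
                                "size": size,
                                "seed": seed,
                                "fold": fold_id,
                                "metric": metric,
                                "value": getattr(ms, metric),
                            }
                        )
    return LearningCurveResult(records=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# baselines


def baselines(X_train, y_train, X_test, y_test, seed=0, include=None):
    """Fit conventional classifiers on flattened features; score the test set.

    Models: L2 logistic regression, linear SVM, RBF SVM, decision tree.
    Dense neural references are built separately via
    :func:`pnet.model.dense_masks_like` / :func:`pnet.model.dense_matched_masks`
    because they need the sparse model's architecture for the comparison.

    Returns ``{name: (MetricSet, scores)}``.
    """
    models = {
        "logistic": LogisticRegression(penalty="l2", max_iter=2000, random_state=seed),
        "svm_linear": SVC(kernel="linear", random_state=seed),
        "svm_rbf": SVC(kernel="rbf", random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
    }
    if include is not None:
        models = {k: v for k, v in models.items() if k in include}
    out = {}
    for name, est in models.items():
        est.fit(X_train, y_train)
        if hasattr(est, "predict_proba"):
            s = est.predict_proba(X_test)[:, 1]
        elif hasattr(est, "decision_function"):
            raw = est.decision_function(X_test)
            s = 1.0 / (1.0 + np.exp(-raw))  # map margins onto [0, 1]
        else:
            s = est.predict(X_test).astype(float)
        out[name] = (compute_metrics(y_test, s), s)
    return out


# ---------------------------------------------------------------------------
# clinical statistics


def chi2_yates(table):
    """Yates-corrected chi-squared on a 2x2 contingency table.

    ``statistic = sum(max(|O - E| - 0.5, 0)^2 / E)`` with the continuity
    correction clamped at zero (so O == E contributes nothing), p-value from
    the chi-squared distribution with one degree of freedom.
    """
    O = np.asarray(table, dtype=np.float64)
    if O.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(O < 0) or not np.all(O == np.round(O)):
        raise ValueError("counts must be non-negative integers")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all table margins must be positive")
    E = np.outer(rows, cols) / O.sum()
    adj = np.maximum(np.abs(O - E) - 0.5, 0.0)
    statistic = float((adj**2 / E).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def logrank_test(times, events, groups):
    """Two-group log-rank test (chi-squared, 1 df, two-sided).

    ``groups`` holds two distinct labels; returns ``(statistic, pvalue)``.
    """
    from lifelines.statistics import logrank_test as _lr

    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    a = groups == labels[0]
    b = groups == labels[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("one group is empty")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _lr(times[a], times[b], event_observed_A=events[a], event_observed_B=events[b])
    return float(res.test_statistic), float(res.p_value)
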