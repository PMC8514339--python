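import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from pnet.evaluation import (
    baselines,
    bootstrap_median_test,
    chi2_yates,
    compare_models,
    compute_metrics,
    delong_test,
    fdr_adjust,
    learning_curve,
    logrank_test,
    make_cv_folds,
    make_splits,
)


def pair_counting_auc(y, s):
    """Brute-force AUC oracle: fraction of correctly ordered (pos, neg) pairs."""
    y = np.asarray(y)
    s = np.asarray(s, float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestSplits:
    def test_hundred_samples_gives_80_10_10(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        sp = make_splits(y, seed=0)
        assert len(sp.test) == 10 and len(sp.validation) == 10 and len(sp.train) == 80

    def test_1013_samples_ceil_rule(self):
        y = np.r_[np.zeros(680), np.ones(333)]
        sp = make_splits(y, seed=1)
        assert len(sp.test) == 102  # ceil(1013 * 0.10), documented rule
        assert len(sp.train) + len(sp.validation) + len(sp.test) == 1013

    def test_same_seed_reproduces(self):
        y = np.r_[np.zeros(60), np.ones(40)]
        a, b = make_splits(y, seed=5), make_splits(y, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_stratification_within_one_sample(self):
        y = np.r_[np.zeros(70), np.ones(30)]
        sp = make_splits(y, seed=3)
        global_frac = 0.3
        for part in (sp.train, sp.validation, sp.test):
            assert abs(y[part].sum() - global_frac * len(part)) <= 1

    def test_small_class_raises(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_splits(np.r_[np.zeros(50), np.ones(5)])


class TestCvFolds:
    def test_perfect_stratification(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        folds = make_cv_folds(y, k=5, seed=0)
        for _, te in folds:
            assert y[te].sum() == 1 and len(te) == 2

    def test_folds_partition_dev_set(self):
        y = np.r_[np.zeros(23), np.ones(17)]
        folds = make_cv_folds(y, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(40))
        for tr, te in folds:
            assert set(tr).isdisjoint(te)

    def test_k_exceeding_minority_raises(self):
        with pytest.raises(ValueError, match="minority"):
            make_cv_folds(np.r_[np.zeros(20), np.ones(3)], k=5)


class TestMetrics:
    def test_textbook_auc_example(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert m.auc == pytest.approx(0.75)  # 3 of 4 pairs ordered correctly

    def test_perfect_separation(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 1.0 and m.auprc == 1.0

    def test_constant_scores_tie_correct_to_half(self):
        m = compute_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == pytest.approx(0.5)

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            assert compute_metrics(y, s).auc == pytest.approx(pair_counting_auc(y, s))

    def test_single_class_flags_rank_metrics(self):
        m = compute_metrics([1, 1, 1], [0.2, 0.6, 0.9])
        assert np.isnan(m.auc) and np.isnan(m.auprc)
        assert m.accuracy >= 0  # threshold metrics still returned
        assert any("single-class" in n for n in m.notes)

    def test_no_positive_predictions_flagged(self):
        m = compute_metrics([0, 1], [0.1, 0.2])
        assert m.precision == 0.0 and m.precision_undefined


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [0, 1, 0, 1, 0, 1]
        s = [0.1, 0.9, 0.3, 0.6, 0.2, 0.8]
        _, _, p = delong_test(y, s, s)
        assert p == 1.0

    def test_auc_estimate_matches_pair_counting(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.4, 0.35, 0.8]
        a, _, _ = delong_test(y, s, [0.5, 0.5, 0.5, 0.5])
        assert a == pytest.approx(0.75)

    def test_symmetric_in_model_order(self, rng):
        y = rng.integers(0, 2, 40)
        y[:5], y[5:10] = 0, 1
        sa, sb = rng.random(40), rng.random(40)
        _, _, p1 = delong_test(y, sa, sb)
        _, _, p2 = delong_test(y, sb, sa)
        assert p1 == pytest.approx(p2)


class TestBootstrap:
    def test_identical_scores_give_p_one(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        s = np.linspace(0, 1, 20)
        assert bootstrap_median_test(y, s, s, metric="auprc", n_boot=50, seed=0) == 1.0

    def test_deterministic_given_seed(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        sa, sb = rng.random(50), rng.random(50)
        p1 = bootstrap_median_test(y, sa, sb, n_boot=200, seed=9)
        p2 = bootstrap_median_test(y, sa, sb, n_boot=200, seed=9)
        assert p1 == p2

    def test_minimum_attainable_p_two_sided(self):
        # one model strictly dominates: the doubled add-one bound is
        # 2 / (n_boot + 1)
        y = np.r_[np.zeros(20), np.ones(20)]
        sa = np.r_[np.zeros(20), np.ones(20)]  # perfect
        sb = 1 - sa  # perfectly wrong
        p = bootstrap_median_test(y, sa, sb, metric="auc", n_boot=199, seed=0)
        assert p == pytest.approx(2.0 / 200.0)


class TestFdr:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_permutation_equivariance(self, rng):
        p = rng.random(10)
        perm = rng.permutation(10)
        np.testing.assert_allclose(fdr_adjust(p)[perm], fdr_adjust(p[perm]))

    def test_adjusted_not_below_raw(self, rng):
        p = rng.random(20)
        assert np.all(fdr_adjust(p) >= p - 1e-12)


class TestChiSquaredYates:
    def test_textbook_table(self):
        stat, p = chi2_yates([[10, 20], [20, 10]])
        assert stat == pytest.approx(5.4)
        # cross-check against scipy's contingency implementation
        scipy_stat = chi2_contingency([[10, 20], [20, 10]], correction=True)[0]
        assert stat == pytest.approx(scipy_stat)
        assert 0 < p < 0.05

    def test_observed_equals_expected_is_zero(self):
        stat, p = chi2_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_yates([[0, 0], [5, 5]])


class TestLogRank:
    def test_identical_groups(self):
        stat, p = logrank_test(
            [1, 2, 1, 2], [1, 1, 1, 1], ["a", "a", "b", "b"]
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # A events at 1, 2; B events at 3, 4 -> statistic ~ 2.88
        stat, _ = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert stat == pytest.approx(2.88, abs=0.01)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="event"):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestLearningCurve:
    @staticmethod
    def _noisy_builder(shift):
        def build(X_tr, y_tr, X_te, seed):
            rng = np.random.default_rng(seed)
            w = np.linalg.lstsq(X_tr, y_tr - 0.5, rcond=None)[0]
            return X_te @ w + shift + rng.normal(0, 1e-6, len(X_te))
        return build

    def test_identical_builders_not_distinguishable(self, rng):
        X = rng.normal(size=(120, 5))
        y = (X[:, 0] > 0).astype(int)
        builders = {"a": self._noisy_builder(0.0), "b": self._noisy_builder(0.0)}
        res = learning_curve(X, y, builders, sizes=[60, 120], k=3, seeds=(0, 1))
        tt = res.t_test("a", "b")
        assert np.all(tt["pvalue"] > 0.2)

    def test_sizes_sorted_and_present(self, rng):
        X = rng.normal(size=(150, 4))
        y = (X[:, 0] > 0).astype(int)
        res = learning_curve(
            X, y, {"m": self._noisy_builder(0.0)}, sizes=[150, 60], k=3, seeds=(0,)
        )
        summ = res.summary()
        assert list(summ["size"]) == [60, 150]

    def test_size_too_small_raises(self, rng):
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError, match="at least"):
            learning_curve(X, y, {"m": self._noisy_builder(0.0)}, sizes=[5], k=5)


class TestBaselines:
    def test_separable_toy_logistic_perfect(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([0, 0, 1, 1])
        out = baselines(X, y, X, y, include=["logistic"])
        assert out["logistic"][0].auc == 1.0

    def test_constant_features_fall_back_to_majority(self):
        X = np.zeros((20, 3))
        y = np.r_[np.zeros(14), np.ones(6)]
        out = baselines(X, y, X, y, include=["logistic", "decision_tree"])
        for name in out:
            assert out[name][0].accuracy == pytest.approx(14 / 20)

    def test_all_four_models_return_metrics(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        out = baselines(X[:40], y[:40], X[40:], y[40:])
        assert set(out) == {"logistic", "svm_linear", "svm_rbf", "decision_tree"}
        for ms, s in out.values():
            assert 0 <= ms.auc <= 1
            assert len(s) == 20


class TestCompareModels:
    def test_adjusted_at_least_raw(self, rng):
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        sa = np.clip(y + rng.normal(0, 0.4, 60), 0, 1)
        sb = rng.random(60)
        res = compare_models(y, sa, sb, n_boot=200, seed=0)
        for r in res:
            assert r.pvalue_adjusted >= r.pvalue - 1e-12
            assert 0 <= r.pvalue_adjusted <= 1
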