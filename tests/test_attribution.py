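import math

import numpy as np
import pandas as pd
import pytest

from pnet.attribution import (
    adjust_importance,
    aggregate_importance,
    deeplift_scores,
    export_importance_report,
    node_activation_analysis,
)
from pnet.network import MaskedNet, sigmoid


def reference_deeplift(net, x, x0):
    """Independent scalar-loop rescale implementation (oracle).

    Computes multipliers node by node with explicit Python loops, following
    the chain rule for multipliers; no code shared with the vectorised path.
    """
    H = net.n_heads

    def fwd(v):
        a = [np.asarray(v, float)]
        z, u, p = [], [], []
        for l, layer in enumerate(net.layers):
            zz = np.array(
                [
                    sum(layer.M[i, j] * layer.W[i, j] * a[l][i] for i in range(layer.M.shape[0]))
                    + layer.b[j]
                    for j in range(layer.M.shape[1])
                ]
            )
            z.append(zz)
            a.append(np.tanh(zz) if net.activations[l] == "tanh" else zz)
        for h in range(H):
            uu = float(a[h + 1] @ net.head_w[h] + net.head_b[h])
            u.append(uu)
            p.append(1 / (1 + math.exp(-uu)) if net.head_activation == "sigmoid" else uu)
        return a, z, u, p

    a, z, u, p = fwd(x)
    a0, z0, u0, p0 = fwd(x0)

    def resc(fz, fz0, zz, zz0, deriv):
        return deriv if abs(zz - zz0) < 1e-7 else (fz - fz0) / (zz - zz0)

    mult = [np.zeros(len(ai)) for ai in a]
    for h in range(H):
        if net.head_activation == "sigmoid":
            r = resc(p[h], p0[h], u[h], u0[h], p0[h] * (1 - p0[h]))
        else:
            r = 1.0
        for i in range(len(a[h + 1])):
            mult[h + 1][i] += (r / H) * net.head_w[h][i]
    for l in range(H, 0, -1):
        layer = net.layers[l - 1]
        for j in range(len(a[l])):
            if net.activations[l - 1] == "tanh":
                r = resc(a[l][j], a0[l][j], z[l - 1][j], z0[l - 1][j], 1 - a0[l][j] ** 2)
            else:
                r = 1.0
            mj = mult[l][j] * r
            for i in range(len(a[l - 1])):
                mult[l - 1][i] += mj * layer.M[i, j] * layer.W[i, j]
    return [mult[l] * (a[l] - a0[l]) for l in range(len(a))]


def random_net(rng, sparse=True):
    widths = [int(rng.integers(2, 6)) for _ in range(rng.integers(2, 4))] + [1]
    masks = []
    for i in range(len(widths) - 1):
        if sparse:
            M = (rng.random((widths[i], widths[i + 1])) < 0.6).astype(float)
            M[rng.integers(widths[i]), :] = 1  # keep at least one live path
        else:
            M = np.ones((widths[i], widths[i + 1]))
        masks.append(M)
    net = MaskedNet(masks, seed=int(rng.integers(1 << 30)))
    for layer in net.layers:  # random trained-looking weights
        layer.W = rng.normal(size=layer.W.shape) * layer.M
        layer.b = rng.normal(size=layer.b.shape) * 0.1
    return net


class TestDeepLift:
    def test_sample_equals_reference_gives_zero(self, rng):
        net = random_net(rng)
        x = rng.normal(size=(1, net.layers[0].M.shape[0]))
        s = deeplift_scores(net, x, reference=x[0])
        for layer_scores in s.sample_scores:
            np.testing.assert_allclose(layer_scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(s.target.delta_t, 0.0, atol=1e-12)

    def test_linear_model_equals_gradient_times_delta(self):
        # identity activations + identity head: the network is t = w2^T W1^T x
        # and rescale must reduce exactly to gradient * (x - x0)
        M = np.ones((2, 1))
        net = MaskedNet([M], seed=0, activations=["identity"], head_activation="identity")
        net.layers[0].W = np.array([[2.0], [0.0]])
        net.layers[0].b = np.zeros(1)
        net.head_w = [np.array([1.0])]
        net.head_b = [0.0]
        s = deeplift_scores(net, np.array([[3.0, 5.0]]), reference=np.zeros(2))
        np.testing.assert_allclose(s.sample_scores[0][0], [6.0, 0.0])
        np.testing.assert_allclose(s.target.delta_t, [6.0])

    def test_single_tanh_unit_closed_form(self):
        # one input, one tanh unit, identity head with unit weight:
        # delta_t = tanh(1) and the sole input's C equals it
        net = MaskedNet(
            [np.ones((1, 1))], seed=0, activations=["tanh"], head_activation="identity"
        )
        net.layers[0].W = np.array([[1.0]])
        net.layers[0].b = np.zeros(1)
        net.head_w = [np.array([1.0])]
        net.head_b = [0.0]
        s = deeplift_scores(net, np.array([[1.0]]), reference=np.zeros(1))
        assert s.target.delta_t[0] == pytest.approx(math.tanh(1.0))
        assert s.sample_scores[0][0, 0] == pytest.approx(0.7616, abs=1e-4)

    def test_matches_scalar_loop_oracle(self, rng):
        for _ in range(10):
            net = random_net(rng)
            d = net.layers[0].M.shape[0]
            x = rng.normal(size=d)
            x0 = rng.normal(size=d) * 0.3
            got = deeplift_scores(net, x[None, :], reference=x0)
            want = reference_deeplift(net, x, x0)
            for l in range(len(want)):
                np.testing.assert_allclose(got.sample_scores[l][0], want[l], atol=1e-10)

    def test_completeness_every_layer(self, rng):
        for _ in range(10):
            net = random_net(rng)
            d = net.layers[0].M.shape[0]
            X = rng.normal(size=(4, d))
            s = deeplift_scores(net, X)
            for l in range(s.n_layers):
                np.testing.assert_allclose(
                    s.sample_scores[l].sum(axis=1), s.delta_t[l], rtol=1e-8, atol=1e-12
                )

    def test_nodes_without_path_get_zero(self):
        # second input feeds nothing (mask column zero in its only row)
        M1 = np.array([[1.0], [0.0]])
        net = MaskedNet([M1, np.ones((1, 1))], seed=0)
        X = np.array([[1.0, 7.0]])
        s = deeplift_scores(net, X)
        assert s.sample_scores[0][0, 1] == 0.0

    def test_untrained_nan_weights_raise(self, rng):
        net = random_net(rng)
        net.layers[0].W[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            deeplift_scores(net, np.zeros((1, net.layers[0].M.shape[0])))


class TestAggregation:
    @pytest.mark.parametrize(
        "scores, expected",
        [([[1.5], [-2.0]], [0.5]), ([[1.0], [2.0]], [3.0]), ([[0.0], [0.0]], [0.0])],
    )
    def test_aggregate_is_abs_of_signed_sum(self, scores, expected):
        np.testing.assert_allclose(aggregate_importance(np.array(scores)), expected)

    def test_uniform_degrees_unchanged(self):
        C = np.array([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(adjust_importance(C, [4, 4, 4]), C)

    def test_hub_adjustment_hand_example(self):
        # 49 nodes d=1, one hub d=50 with C=10: mu=1.98, sigma~6.861,
        # threshold ~36.28 < 50 -> hub score 10/50 = 0.2
        d = np.r_[np.ones(49), [50.0]]
        C = np.r_[np.full(49, 2.0), [10.0]]
        out = adjust_importance(C, d)
        assert out[-1] == pytest.approx(0.2)
        np.testing.assert_array_equal(out[:-1], C[:-1])

    def test_two_node_example_not_adjusted(self):
        # degrees {1, 2}: mu=1.5, sigma=0.5, threshold 4 -> unchanged
        C = np.array([5.0, 7.0])
        np.testing.assert_array_equal(adjust_importance(C, [1, 2]), C)

    def test_adjustment_never_increases(self, rng):
        for _ in range(20):
            n = rng.integers(2, 40)
            C = rng.random(n) * 10
            d = rng.integers(0, 100, n)
            out = adjust_importance(C, d)
            assert np.all(out <= C + 1e-12)


class TestActivationAnalysis:
    def test_identical_distributions_give_zero_statistic(self, rng):
        net = random_net(rng, sparse=False)
        d = net.layers[0].M.shape[0]
        X = np.tile(rng.normal(size=(5, d)), (2, 1))
        y = np.r_[np.zeros(5), np.ones(5)]
        prof = node_activation_analysis(net, X, y)
        for t in prof.statistic:
            np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_zero_fan_in_node_is_degenerate(self):
        M = np.array([[1.0, 0.0]])  # second unit: activation tanh(b), constant
        net = MaskedNet([M], seed=0)
        X = np.array([[0.1], [0.9], [0.5], [0.3]])
        prof = node_activation_analysis(net, X, np.array([0, 1, 0, 1]))
        assert bool(prof.degenerate[1][1])
        assert prof.statistic[1][1] == 0.0

    def test_driver_pathway_ranks_high(self):
        from pnet import PNet, TrainingConfig, synthetic

        cohort = synthetic.generate(
            synthetic.SimulationConfig(n_samples=500, p1=0.5, p0=0.01, n_drivers=1, seed=2)
        )
        net = cohort.build_network()
        res = PNet(
            cohort.tensor, cohort.labels, net, config=TrainingConfig(epochs=60, seed=2)
        ).fit()
        prof = node_activation_analysis(res, cohort.tensor.flatten(), cohort.y)
        layer = 2  # leaf pathway layer
        stat = np.abs(prof.statistic[layer])
        names = prof.node_names[layer]
        driver_idx = names.index(cohort.driver_pathways[0])
        cutoff = np.quantile(stat, 0.95)
        assert stat[driver_idx] >= cutoff


class TestReport:
    def test_report_tables_and_links(self, tmp_path, trained):
        res = trained["results"]
        scores = res.explain(trained["X"][:30])
        outdir = export_importance_report(scores, trained["net"], tmp_path)
        layer2 = pd.read_csv(tmp_path / "importance_layer2.csv")
        ranks = sorted(layer2["rank"])
        assert ranks == list(range(1, len(layer2) + 1))
        top = layer2.loc[layer2["rank"] == 1].iloc[0]
        assert top["adjusted_C"] == layer2["adjusted_C"].max()
        links = pd.read_csv(tmp_path / "links.csv")
        # conservation: shares out of a node sum to its own share
        l2_nodes = set(layer2["node_id"])
        share = layer2.set_index("node_id")["adjusted_C"] / layer2["adjusted_C"].sum()
        sums = links[links["source_node"].isin(l2_nodes)].groupby("source_node")["share"].sum()
        for node, s in sums.items():
            assert s == pytest.approx(share[node])

    def test_empty_evaluation_set_raises(self, trained):
        res = trained["results"]
        scores = res.explain(trained["X"][:5])
        scores.sample_scores = [s[:0] for s in scores.sample_scores]
        with pytest.raises(ValueError, match="empty"):
            export_importance_report(scores, trained["net"], "/tmp/should_not_exist_dir")
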