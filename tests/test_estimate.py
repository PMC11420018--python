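import numpy as np
import pandas as pd
import pytest

import ersnet as e
from ersnet.estimate import EstimationSettings, ebic_score
from ersnet.items import NodeMeta
from ersnet.network import WeightedNetwork


def _continuous_nodes(names):
    return [NodeMeta(n, "continuous_strategy", "ER", (0, 1)) for n in names]


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        frame = pd.DataFrame({"a": [1, 2, 3, 5], "b": [1, 2, 3, 5]})
        corr = e.correlation_matrix(frame)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_exact_linear_pair(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 4, 6, 8]})
        assert e.correlation_matrix(frame).loc["x", "y"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.standard_normal((10_000, 4)), columns=list("abcd"))
        corr = e.correlation_matrix(frame).to_numpy()
        off = corr[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.05

    def test_constant_column_named_in_error(self):
        frame = pd.DataFrame({"ok": [1, 2, 3], "flat": [2, 2, 2]})
        with pytest.raises(ValueError, match="flat"):
            e.correlation_matrix(frame)

    def test_symmetry_unit_diagonal(self, default_data):
        corr = e.correlation_matrix(default_data.ress_matrix(), method="spearman")
        a = corr.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert np.abs(a).max() <= 1 + 1e-12


class TestEbicGlasso:
    def test_identity_correlation_gives_empty_network(self):
        net = e.ebic_glasso(np.eye(6), n=500)
        assert net.n_edges == 0

    def test_block_structure_recovered(self):
        # analytic oracle: inverting the 2-block [[1,.8],[.8,1]] plus an
        # independent third variable gives partial correlations (.8, 0, 0)
        corr = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.0], [0.0, 0.0, 1.0]])
        net = e.ebic_glasso(corr, n=500, node_ids=["a", "b", "c"])
        assert net.weights[0, 1] > 0.5
        assert net.weights[0, 2] == 0.0
        assert net.weights[1, 2] == 0.0

    def test_ebic_prefers_sparser_fit_at_equal_loglik(self):
        for gamma in (0.0, 0.5, 1.0):
            assert ebic_score(-100.0, 5, 376, 22, gamma) < ebic_score(-100.0, 7, 376, 22, gamma)

    def test_edge_count_shrinks_with_gamma(self, default_data):
        corr = e.correlation_matrix(default_data.ress_matrix())
        counts = []
        for gamma in (0.0, 0.5, 1.0):
            net = e.ebic_glasso(corr, n=default_data.n, settings=EstimationSettings(ebic_gamma=gamma))
            counts.append(net.n_edges)
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            e.ebic_glasso(np.eye(3), n=0)
        with pytest.raises(ValueError):
            e.ebic_glasso(np.eye(3), n=100, settings=EstimationSettings(n_lambda=0))

    def test_partial_correlations_bounded(self, default_data):
        corr = e.correlation_matrix(default_data.ress_matrix())
        net = e.ebic_glasso(corr, n=default_data.n)
        assert np.abs(net.weights).max() <= 1.0
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)


def _clique_block(p, weight):
    w = np.full((p, p), weight)
    np.fill_diagonal(w, 0.0)
    return w


class TestWalktrap:
    def test_two_disconnected_cliques(self):
        w = np.zeros((8, 8))
        w[:4, :4] = _clique_block(4, 0.5)
        w[4:, 4:] = _clique_block(4, 0.5)
        net = WeightedNetwork([f"n{i}" for i in range(8)], w, "ebic_glasso")
        part = e.walktrap_communities(net)
        assert part.n_communities == 2
        labels = part.labels(net.node_ids)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_isolated_node_is_own_community(self):
        w = np.zeros((5, 5))
        w[:4, :4] = _clique_block(4, 0.5)
        net = WeightedNetwork([f"n{i}" for i in range(5)], w, "ebic_glasso")
        part = e.walktrap_communities(net)
        assert part.n_communities == 2
        labels = part.labels(net.node_ids)
        assert labels[4] not in labels[:4]

    def test_component_count_lower_bounds_communities(self):
        rng = np.random.default_rng(0)
        for k in (2, 3):
            blocks = []
            for _ in range(k):
                size = rng.integers(3, 6)
                blocks.append(_clique_block(size, float(rng.uniform(0.2, 0.8))))
            p = sum(b.shape[0] for b in blocks)
            w = np.zeros((p, p))
            at = 0
            for b in blocks:
                s = b.shape[0]
                w[at : at + s, at : at + s] = b
                at += s
            net = WeightedNetwork([f"n{i}" for i in range(p)], w, "ebic_glasso")
            assert e.walktrap_communities(net).n_communities >= k

    def test_empty_network_rejected(self):
        net = WeightedNetwork([], np.zeros((0, 0)), "ebic_glasso")
        with pytest.raises(ValueError):
            e.walktrap_communities(net)

    def test_negative_weights_treated_by_magnitude(self):
        w = np.zeros((8, 8))
        w[:4, :4] = -_clique_block(4, 0.5)
        w[4:, 4:] = _clique_block(4, 0.5)
        net = WeightedNetwork([f"n{i}" for i in range(8)], w, "ebic_glasso")
        assert e.walktrap_communities(net).n_communities == 2


class TestEstimateMgm:
    def test_gaussian_chain_recovered(self):
        # conditional-independence oracle: the generating precision is a
        # chain A-B-C, so A and C share no edge given B
        K = np.array([[1.0, -0.5, 0.0], [-0.5, 1.0, -0.5], [0.0, -0.5, 1.0]])
        cov = np.linalg.inv(K)
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(np.zeros(3), cov, size=2000)
        tab = pd.DataFrame(X, columns=["A", "B", "C"])
        net = e.estimate_mgm(tab, _continuous_nodes(["A", "B", "C"]))
        assert net.weights[0, 1] > 0.2
        assert net.weights[1, 2] > 0.2
        assert abs(net.weights[0, 2]) < 0.05

    def test_duplicate_column_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        tab = pd.DataFrame({"A": x, "B": x.copy(), "C": rng.standard_normal(200)})
        with pytest.raises(ValueError, match="duplicate"):
            e.estimate_mgm(tab, _continuous_nodes(["A", "B", "C"]))

    def test_too_few_rows_rejected(self):
        tab = pd.DataFrame(np.random.default_rng(0).standard_normal((20, 3)), columns=list("ABC"))
        with pytest.raises(ValueError, match="50"):
            e.estimate_mgm(tab, _continuous_nodes(list("ABC")))

    def test_null_model_mostly_empty(self):
        # CV-min lasso is not selection-consistent: expect mostly-empty
        # networks with occasional spurious edges under the default rule,
        # and (near-)certain emptiness under the sparser 1-SE rule
        nodes = _continuous_nodes([f"v{i}" for i in range(5)])
        counts_min, counts_1se = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tab = pd.DataFrame(
                rng.standard_normal((2000, 5)), columns=[n.node_id for n in nodes]
            )
            net = e.estimate_mgm(tab, nodes, EstimationSettings(cv_seed=seed))
            counts_min.append(net.n_edges)
            net1 = e.estimate_mgm(tab, nodes, EstimationSettings(cv_seed=seed, cv_rule="1se"))
            counts_1se.append(net1.n_edges)
        assert sum(c == 0 for c in counts_min) >= 5
        assert max(counts_min) <= 5
        assert sum(c == 0 for c in counts_1se) >= int(0.95 * len(counts_1se))

    def test_fitted_network_contract(self, fitted_mgm):
        net = fitted_mgm
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert net.means is not None and net.sds is not None
        assert np.all(net.residual_sd > 0)
        assert net.groups is not None and len(net.groups) == 22
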