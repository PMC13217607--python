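import numpy as np
import pytest

from enzgraph.graphs import ProteinGraph
from enzgraph.model import (Adam, GraphEnzymeClassifier, ModelConfig,
                            clustergcn_forward, focal_loss, init_params,
                            leconv_forward, load_checkpoint, model_forward,
                            save_checkpoint, train_model)

from conftest import random_graph

# ---------------------------------------------------------------------------
# independent dense oracles
# ---------------------------------------------------------------------------


def leconv_oracle(H, A, W1, W2, W3):
    """Literal per-node double loop of the local-extremum convolution."""
    L = H.shape[0]
    out = np.zeros((L, W1.shape[1]))
    for i in range(L):
        acc = H[i] @ W1
        for j in range(L):
            if A[i, j]:
                acc = acc + (H[i] @ W2 - H[j] @ W3)
        out[i] = np.maximum(acc, 0.0)
    return out


def clustergcn_oracle(H, A, W1, W2, lam):
    """Dense-matrix evaluation using an explicit inverse."""
    L = A.shape[0]
    D = np.diag(A.sum(axis=1))
    A_hat = np.linalg.inv(D + np.eye(L)) @ (A + np.eye(L))
    M = A_hat + lam * np.diag(np.diag(A_hat))
    return np.maximum(M @ H @ W1 + H @ W2, 0.0)


def tiny_config(input_dim=23, n_classes=2, **kw):
    defaults = dict(layer_dims=(3, 3), n_leconv=1, n_clustergcn=1,
                    fc_dims=(4, 3), lambda_diag=1.0, seed=0)
    defaults.update(kw)
    return ModelConfig(input_dim=input_dim, n_classes=n_classes, **defaults)


def model_oracle(graph, params, config):
    """End-to-end hand computation for a 1 LEConv + 1 ClusterGCN config."""
    H = graph.node_input
    A = graph.adjacency
    H = leconv_oracle(H, A, params["leconv0_W1"].value,
                      params["leconv0_W2"].value, params["leconv0_W3"].value)
    H = clustergcn_oracle(H, A, params["cluster0_W1"].value,
                          params["cluster0_W2"].value, config.lambda_diag)
    v = H.mean(axis=0)
    v = np.maximum(v @ params["fc0_W"].value + params["fc0_b"].value, 0.0)
    v = np.maximum(v @ params["fc1_W"].value + params["fc1_b"].value, 0.0)
    z = v @ params["out_W"].value + params["out_b"].value
    return 1.0 / (1.0 + np.exp(-z))


def make_graph(rng, L, n_classes=2, emb_dim=3):
    _, A = random_graph(rng, L, 1)
    X = np.zeros((L, 20))
    X[np.arange(L), rng.integers(0, 20, size=L)] = 1.0
    E = rng.standard_normal((L, emb_dim))
    y = rng.integers(0, 2, size=n_classes).astype(np.int8)
    return ProteinGraph(features=X, adjacency=A, embeddings=E, target=y,
                        chain_ref=f"g{L}")


# ---------------------------------------------------------------------------
# layer semantics
# ---------------------------------------------------------------------------


class TestLEConv:
    def test_isolated_node(self):
        out = leconv_forward(np.array([[1.0]]), np.zeros((1, 1)),
                             np.array([[2.0]]), np.array([[5.0]]),
                             np.array([[7.0]]))
        np.testing.assert_allclose(out, [[2.0]])

    def test_relu_clamps(self):
        out = leconv_forward(np.array([[1.0]]), np.zeros((1, 1)),
                             np.array([[-2.0]]), np.array([[0.0]]),
                             np.array([[0.0]]))
        np.testing.assert_allclose(out, [[0.0]])

    def test_two_node_oracle(self):
        rng = np.random.default_rng(0)
        H = rng.standard_normal((2, 2))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        W = [rng.standard_normal((2, 2)) for _ in range(3)]
        np.testing.assert_allclose(leconv_forward(H, A, *W),
                                   leconv_oracle(H, A, *W), atol=1e-6)

    def test_random_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            L = int(rng.integers(1, 11))
            H, A = random_graph(rng, L, 4)
            W = [rng.standard_normal((4, 3)) for _ in range(3)]
            np.testing.assert_allclose(leconv_forward(H, A, *W),
                                       leconv_oracle(H, A, *W), atol=1e-6)


class TestClusterGCN:
    def test_single_node_hand_value(self):
        # A~ = 1 for an isolated node; ReLU((1+1)*1*1 + 1*1) = 3
        out = clustergcn_forward(np.array([[1.0]]), np.zeros((1, 1)),
                                 np.array([[1.0]]), np.array([[1.0]]),
                                 lambda_diag=1.0)
        np.testing.assert_allclose(out, [[3.0]])

    def test_zero_weights(self):
        rng = np.random.default_rng(0)
        H, A = random_graph(rng, 5, 3)
        out = clustergcn_forward(H, A, np.zeros((3, 2)), np.zeros((3, 2)))
        np.testing.assert_array_equal(out, np.zeros((5, 2)))

    def test_random_oracle_equivalence(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            L = int(rng.integers(1, 11))
            H, A = random_graph(rng, L, 3)
            W1, W2 = (rng.standard_normal((3, 2)) for _ in range(2))
            lam = float(rng.uniform(0, 2))
            np.testing.assert_allclose(
                clustergcn_forward(H, A, W1, W2, lam),
                clustergcn_oracle(H, A, W1, W2, lam), atol=1e-6)


class TestModelForward:
    def test_zero_output_layer_gives_half(self):
        rng = np.random.default_rng(0)
        config = tiny_config()
        params = init_params(config)
        params["out_W"].value[:] = 0.0
        params["out_b"].value[:] = 0.0
        g = make_graph(rng, 5)
        np.testing.assert_allclose(model_forward(g, params, config),
                                   [0.5, 0.5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        config = tiny_config()
        params = init_params(config)
        g = make_graph(rng, 7)
        perm = rng.permutation(7)
        g2 = ProteinGraph(features=g.features[perm],
                          adjacency=g.adjacency[np.ix_(perm, perm)],
                          embeddings=g.embeddings[perm], target=g.target)
        np.testing.assert_allclose(model_forward(g, params, config),
                                   model_forward(g2, params, config),
                                   atol=1e-12)

    def test_composed_oracle(self):
        rng = np.random.default_rng(2)
        config = tiny_config()
        for _ in range(100):
            params = init_params(tiny_config(seed=int(rng.integers(1000))))
            g = make_graph(rng, int(rng.integers(2, 11)))
            np.testing.assert_allclose(model_forward(g, params, config),
                                       model_oracle(g, params, config),
                                       atol=1e-6)

    def test_probabilities_in_open_interval(self):
        rng = np.random.default_rng(3)
        config = tiny_config()
        params = init_params(config)
        p = model_forward(make_graph(rng, 9), params, config)
        assert np.all((p > 0) & (p < 1))

    def test_dim_mismatch(self):
        rng = np.random.default_rng(4)
        config = tiny_config(input_dim=30)
        params = init_params(config)
        with pytest.raises(ValueError):
            model_forward(make_graph(rng, 5), params, config)


class TestFocalLoss:
    def test_well_classified_vanishes(self):
        assert focal_loss(np.array([0.999999]), np.array([1]), 2.0) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_gamma_zero_is_bce(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99, size=12)
        y = rng.integers(0, 2, size=12)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, gamma=0.0) == pytest.approx(bce, abs=1e-8)

    def test_hand_value(self):
        # p=0.5, y=1, gamma=2: (1-0.5)^2 * ln 2
        assert focal_loss(np.array([0.5]), np.array([1]), 2.0) == \
            pytest.approx(0.25 * np.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("gamma", [1.0, 2.0, 3.0, 4.0])
    def test_focal_bounded_by_bce(self, gamma):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.01, 0.99, size=200)
        y = rng.integers(0, 2, size=200)
        pt = np.where(y == 1, p, 1 - p)
        focal_terms = -((1 - pt) ** gamma) * np.log(pt)
        bce_terms = -np.log(pt)
        assert np.all(focal_terms <= bce_terms + 1e-12)

    def test_extreme_probabilities_clamped(self):
        val = focal_loss(np.array([0.0, 1.0]), np.array([1, 0]), 2.0)
        assert np.isfinite(val)


class TestGradientCheck:
    def test_focal_gradient_matches_finite_differences(self):
        """Analytic gradients through a 1-layer model vs central differences."""
        rng = np.random.default_rng(0)
        config = ModelConfig(input_dim=23, n_classes=2, layer_dims=(3,),
                             n_leconv=1, n_clustergcn=0, fc_dims=(4, 3),
                             seed=1)
        params = init_params(config)
        g = make_graph(rng, 4)

        from enzgraph._autodiff import as_tensor
        from enzgraph.model import _forward_t

        def loss_value() -> float:
            return focal_loss(model_forward(g, params, config), g.target, 2.0)

        probs = _forward_t(as_tensor(g.node_input), g.adjacency, params,
                           config)
        focal_loss(probs, g.target, 2.0).backward()
        eps = 1e-6
        for key in ("leconv0_W1", "fc0_W", "out_W", "out_b"):
            analytic = params[key].grad
            numeric = np.zeros_like(analytic)
            it = np.nditer(params[key].value, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = params[key].value[idx]
                params[key].value[idx] = orig + eps
                up = loss_value()
                params[key].value[idx] = orig - eps
                down = loss_value()
                params[key].value[idx] = orig
                numeric[idx] = (up - down) / (2 * eps)
            scale = np.maximum(np.abs(numeric), 1e-3)
            assert np.max(np.abs(analytic - numeric) / scale) < 1e-4


class TestTraining:
    def make_separable(self, rng, n_per_class=8, L=12):
        graphs = []
        for label in (0, 1):
            for _ in range(n_per_class):
                g = make_graph(rng, L, n_classes=2)
                X = np.zeros((L, 20))
                col = 0 if label == 0 else 5
                X[:, col] = 1.0
                y = np.array([1, 0] if label == 0 else [0, 1], dtype=np.int8)
                graphs.append(ProteinGraph(features=X, adjacency=g.adjacency,
                                           embeddings=g.embeddings, target=y))
        return graphs

    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(0)
        graphs = self.make_separable(rng)
        config = tiny_config(lr=3e-3, max_epochs=30, patience=30,
                             batch_size=8)
        params, log = train_model(graphs[2:14], graphs[:2] + graphs[14:],
                                  config)
        assert log.epochs[-1]["train_loss"] < log.epochs[0]["train_loss"]

    def test_same_seed_same_trajectory(self):
        rng = np.random.default_rng(1)
        graphs = self.make_separable(rng, n_per_class=4)
        config = tiny_config(lr=1e-3, max_epochs=8, patience=30, batch_size=4)
        _, log1 = train_model(graphs[:6], graphs[6:], config)
        _, log2 = train_model(graphs[:6], graphs[6:], config)
        assert log1.epochs == log2.epochs

    def test_patience_one_frozen_stops_after_two_epochs(self):
        rng = np.random.default_rng(2)
        graphs = self.make_separable(rng, n_per_class=2)
        config = tiny_config(lr=0.0, max_epochs=50, patience=1, batch_size=4)
        _, log = train_model(graphs[:2], graphs[2:], config)
        assert len(log.epochs) == 2

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train_model([], [], tiny_config())


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        config = tiny_config()
        params = init_params(config)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, config, ["1.1.1.1", "2.1.1.1"])
        p2, c2, classes = load_checkpoint(path)
        assert c2 == config
        assert classes == ["1.1.1.1", "2.1.1.1"]
        for k in params:
            np.testing.assert_array_equal(params[k].value, p2[k].value)


class TestEstimator:
    def test_get_set_params(self):
        est = GraphEnzymeClassifier(lr=1e-3)
        assert est.get_params()["lr"] == 1e-3
        est.set_params(gamma=3.0)
        assert est.gamma == 3.0
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_predict_shapes(self):
        rng = np.random.default_rng(3)
        graphs = [make_graph(rng, 8) for _ in range(10)]
        est = GraphEnzymeClassifier(layer_dims=(4, 4, 4), fc_dims=(4, 4),
                                    max_epochs=3, patience=30, batch_size=5,
                                    seed=0)
        est.fit(graphs)
        probs = est.predict_proba(graphs)
        assert probs.shape == (10, 2)
        assert est.predict(graphs).shape == (10, 2)
        assert hasattr(est, "config_") and hasattr(est, "history_")

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError):
            GraphEnzymeClassifier().predict_proba([])

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        graphs = [make_graph(rng, 8) for _ in range(8)]
        est = GraphEnzymeClassifier(layer_dims=(4, 4, 4), fc_dims=(4, 4),
                                    max_epochs=2, patience=30, batch_size=4)
        est.fit(graphs)
        est.save(tmp_path / "m.npz")
        est2, _ = GraphEnzymeClassifier.load(tmp_path / "m.npz")
        np.testing.assert_allclose(est.predict_proba(graphs),
                                   est2.predict_proba(graphs))
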