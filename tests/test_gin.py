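"""GIN layer/readout oracles, gradient checks, and the training loop."""

import numpy as np
import pytest

from loopclust.gin import (
    GINEmbedder,
    ModelConfig,
    embed,
    gin_layer,
    load_checkpoint,
    predict,
    readout,
    save_checkpoint,
    train,
)
from loopclust.graphs import encode_loops
from loopclust.synthetic import NoiseSpec, generate_dataset, internal_templates

from conftest import make_loop


class TestGinLayerOracle:
    def test_sum_aggregation_eps_zero(self):
        # eps = 0, identity MLP: h'_v = h_v + sum_{u != v} h_u = column sum
        H = np.array([[1.0, 2.0], [3.0, 5.0], [-1.0, 0.0]])
        out = gin_layer(H, epsilon=0.0)
        expected = np.tile(H.sum(axis=0), (3, 1))
        np.testing.assert_allclose(out, expected)

    def test_eps_half_hand_values(self):
        # h'_v = (1 + 0.5) h_v + (total - h_v) = 0.5 h_v + total
        H = np.array([[2.0, 0.0], [0.0, 4.0]])
        out = gin_layer(H, epsilon=0.5)
        np.testing.assert_allclose(out, [[3.0, 4.0], [2.0, 6.0]])

    def test_mlp_applied_after_aggregation(self):
        H = np.array([[1.0], [2.0]])
        out = gin_layer(H, epsilon=0.0, mlp=lambda a: a * 10.0)
        np.testing.assert_allclose(out, [[30.0], [30.0]])

    def test_project_add_matches_explicit_edge_loop(self, hand_loop):
        from loopclust.graphs import encode_loop

        g = encode_loop(hand_loop)
        n = g.n_nodes
        rng = np.random.default_rng(0)
        H = rng.normal(size=(n, 4))
        P = rng.normal(size=(23, 4))
        out = gin_layer(H, graph=g, epsilon=0.0, edge_mode="project_add", edge_projection=P)
        # independent oracle: explicit sum over incoming edges per node
        for v in range(n):
            msg = np.zeros(4)
            for u in range(n):
                if u != v:
                    msg += H[u] + g.edge_features[u, v] @ P
            np.testing.assert_allclose(out[v], H[v] + msg, atol=1e-10)

    def test_project_add_requires_graph(self):
        with pytest.raises(ValueError):
            gin_layer(np.zeros((2, 4)), edge_mode="project_add")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="edge_mode"):
            gin_layer(np.zeros((2, 4)), edge_mode="mean")


class TestReadoutOracle:
    def test_hand_values(self):
        layers = [np.array([[2.0, -4.0], [4.0, 0.0]]), np.array([[1.0, 1.0], [1.0, 1.0]])]
        # means: [3, -2] and [1, 1]; sum [4, -1]; LeakyReLU(0.01) -> [4, -0.01]
        np.testing.assert_allclose(readout(layers), [4.0, -0.01])

    def test_projection_and_bias(self):
        layers = [np.array([[2.0, 2.0]])]
        W = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        b = np.array([0.5, 0.5, 0.5])
        np.testing.assert_allclose(readout(layers, W, b), [2.5, 2.5, 4.5])


def _tiny_graphs(n=8, seed=0):
    templates = internal_templates()[:2]
    ds = generate_dataset(templates, n_per_family=n, noise=NoiseSpec(seed=seed), seed=seed)
    return encode_loops(ds.loops), ds


class TestGradientCheck:
    def test_analytic_gradients_match_finite_differences(self):
        """Central-difference check of the manual backprop on a tiny model."""
        graphs, _ = _tiny_graphs(n=3)
        est = GINEmbedder(num_layers=2, hidden_dim=6, embed_dim=4, seed=0,
                          learn_epsilon=True, epsilon=0.1)
        est.classes_ = np.array(["A", "B"])
        rng = np.random.default_rng(1)
        params = est._init_params(rng)
        from loopclust.gin import _pack

        X, Ein, mask, nvec = _pack(graphs[:4])
        Y = np.array([0, 1, 0, 1])
        _, grads, _ = est._loss_and_grads(params, X, Ein, mask, nvec, Y)
        h = 1e-6
        check_rng = np.random.default_rng(2)
        for key in params:
            flat = params[key].reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _, _ = est._loss_and_grads(params, X, Ein, mask, nvec, Y)
                flat[idx] = orig - h
                lm, _, _ = est._loss_and_grads(params, X, Ein, mask, nvec, Y)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, abs=2e-5), key


class TestFitBehaviour:
    def test_requires_labels_and_classes(self):
        graphs, _ = _tiny_graphs(n=3)
        est = GINEmbedder(epochs=1)
        with pytest.raises(ValueError):
            est.fit(graphs, ["A"] * len(graphs))  # single class
        with pytest.raises(ValueError):
            est.fit(graphs, ["A"])  # length mismatch
        with pytest.raises(ValueError):
            est.fit([], [])

    def test_unfitted_transform_raises(self):
        graphs, _ = _tiny_graphs(n=3)
        with pytest.raises(RuntimeError, match="not fitted"):
            GINEmbedder().transform(graphs)

    def test_deterministic_under_seed(self):
        graphs, ds = _tiny_graphs(n=6)
        cfg = ModelConfig(num_layers=2, hidden_dim=16, embed_dim=8, epochs=5, seed=11)
        split = (ds.split["train"], ds.split["val"], ds.split["test"])
        m1 = train(graphs, split, cfg)
        m2 = train(graphs, split, ModelConfig(**{**cfg.__dict__}))
        for key, val in m1.embedder.params_.items():
            np.testing.assert_array_equal(val, m2.embedder.params_[key])
        assert m1.history == m2.history
        np.testing.assert_array_equal(embed(graphs, m1), embed(graphs, m2))

    def test_learns_two_easy_families(self):
        graphs, ds = _tiny_graphs(n=12, seed=3)
        cfg = ModelConfig(num_layers=2, hidden_dim=32, embed_dim=16, epochs=40, seed=3)
        model = train(graphs, (ds.split["train"], ds.split["val"], ds.split["test"]), cfg)
        assert model.best_val_accuracy == 1.0
        assert model.test_accuracy == 1.0
        labels, probs = predict(graphs, model)
        assert probs.shape == (len(graphs), 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        truth = np.array([g.label for g in graphs])
        assert np.mean(labels == truth) == 1.0

    def test_embedding_shape_and_order(self):
        graphs, ds = _tiny_graphs(n=4)
        cfg = ModelConfig(num_layers=1, hidden_dim=8, embed_dim=5, epochs=2, seed=0)
        model = train(graphs, (ds.split["train"], ds.split["val"], ds.split["test"]), cfg)
        emb = model.embedder.transform(graphs)
        assert emb.shape == (len(graphs), 5)
        # transform respects input order: per-graph forward agrees with batch
        single = np.vstack([model.embedder.transform([g]) for g in graphs])
        np.testing.assert_allclose(emb, single, atol=1e-9)

    def test_checkpoint_round_trip(self, tmp_path):
        graphs, ds = _tiny_graphs(n=4)
        cfg = ModelConfig(num_layers=1, hidden_dim=8, embed_dim=5, epochs=2, seed=0)
        model = train(graphs, (ds.split["train"], ds.split["val"], ds.split["test"]), cfg)
        save_checkpoint(model, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_allclose(
            back.embedder.transform(graphs), model.embedder.transform(graphs), atol=1e-12
        )
        assert back.label_vocabulary == model.label_vocabulary
        assert back.best_val_accuracy == model.best_val_accuracy

    def test_schema_mismatch_rejected(self):
        graphs, ds = _tiny_graphs(n=4)
        cfg = ModelConfig(num_layers=1, hidden_dim=8, embed_dim=5, epochs=1, seed=0)
        model = train(graphs, (ds.split["train"], ds.split["val"], ds.split["test"]), cfg)
        bad = encode_loops([make_loop()])[0]
        bad.edge_features = bad.edge_features[:, :, :20]
        with pytest.raises(ValueError, match="schema"):
            model.embedder.transform([bad])
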