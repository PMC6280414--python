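import numpy as np
import pytest

from pgmelm import (adaptive_structure, confusion, elm_ae_fit, elm_fit,
                    elm_solve, helm_forward, load_model, make_imbalanced,
                    pgmelm_fit, predict, save_model, split, welm_fit,
                    SynthSpec)
from pgmelm.elm import orthogonal_random_weights, sigmoid


def _primal(H, T, C):
    L = H.shape[1]
    return np.linalg.solve(np.eye(L) / C + H.T @ H, H.T @ T)


class TestELMSolve:
    def test_identity_recovers_targets(self):
        T = np.arange(1.0, 5.0)[:, None]
        beta = elm_solve(np.eye(4), T, C=1e8)
        np.testing.assert_allclose(beta, T, atol=1e-6)

    def test_dual_equals_primal_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, L = rng.integers(2, 21), rng.integers(1, 21)
            H = rng.normal(size=(n, L))
            T = rng.normal(size=(n, 1))
            C = float(10 ** rng.uniform(-2, 2))
            np.testing.assert_allclose(elm_solve(H, T, C), _primal(H, T, C),
                                       atol=1e-8)

    def test_large_C_approaches_pseudoinverse(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=(10, 4))
        T = rng.normal(size=(10, 1))
        beta = elm_solve(H, T, C=1e8)
        np.testing.assert_allclose(beta, np.linalg.pinv(H) @ T, atol=1e-5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            elm_solve(np.array([[np.inf]]), np.array([[1.0]]), 1.0)
        with pytest.raises(ValueError):
            elm_solve(np.eye(2), np.eye(2), C=0.0)


class TestELMAE:
    def test_l1_zero_matches_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        beta = elm_ae_fit(X, nodes=4, l1=0.0, iters=500, seed=1)
        a, b = orthogonal_random_weights(5, 4, np.random.default_rng(1))
        H = sigmoid(X @ a + b)
        beta_ls = np.linalg.lstsq(H, X, rcond=None)[0]
        np.testing.assert_allclose(beta, beta_ls, atol=1e-4)

    def test_zero_input_gives_zero_weights(self):
        beta = elm_ae_fit(np.zeros((10, 3)), nodes=2, l1=1e-3, seed=0)
        np.testing.assert_array_equal(beta, 0.0)

    def test_objective_decreases(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 5))
        _, trace = elm_ae_fit(X, nodes=6, l1=1e-3, iters=100, seed=2,
                              return_trace=True)
        assert trace[99] <= trace[0]

    def test_l1_shrinks_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        b0 = elm_ae_fit(X, nodes=5, l1=0.0, iters=200, seed=3)
        b1 = elm_ae_fit(X, nodes=5, l1=10.0, iters=200, seed=3)
        assert np.abs(b1).sum() < np.abs(b0).sum()


class TestAdaptiveStructure:
    @pytest.mark.parametrize("args,expected", [
        ((100, 20, 160, 5, 0.75), (26, 4)),    # ceil(1.25 + 24), ceil(3.75)
        ((100, 20, 100, 5, 0.0), (5, 1)),      # balanced limit, Q clamped
        ((250, 8, 432, 5, 0.8125), None),      # Q = ceil(4.0625) = 5
    ])
    def test_worked_examples(self, args, expected):
        p, q = adaptive_structure(*args)
        if expected is not None:
            assert (p, q) == expected
        else:
            assert q == 5

    def test_monotone_in_delta_ir(self):
        grid = np.linspace(0.0, 0.95, 30)
        pq = [adaptive_structure(120, 10, 200, 6, d) for d in grid]
        ps, qs = zip(*pq)
        assert all(b >= a for a, b in zip(ps, ps[1:]))
        assert all(b >= a for a, b in zip(qs, qs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adaptive_structure(0, 5, 10, 2, 0.5)
        with pytest.raises(ValueError):
            adaptive_structure(10, 5, 10, 2, 1.0)


class TestHELMForward:
    def _model(self, dims, seed=0):
        from pgmelm.elm import ELMLayer, MLELMModel
        rng = np.random.default_rng(seed)
        layers = [ELMLayer(beta=rng.normal(size=(a, b)))
                  for a, b in zip(dims, dims[1:])]
        return MLELMModel(layers=layers, n_nodes=dims[-1], n_layers=len(layers))

    def test_matches_unrolled_loop(self):
        model = self._model([4, 5, 5, 5])
        X = np.random.default_rng(1).normal(size=(5, 4))
        cur = X
        for layer in model.layers:
            cur = 1.0 / (1.0 + np.exp(-(cur @ layer.beta)))
        np.testing.assert_allclose(helm_forward(X, model), cur, atol=1e-12)

    def test_sigmoid_range_and_single_layer(self):
        model = self._model([3, 7])
        X = np.random.default_rng(2).normal(size=(6, 3)) * 10
        out = helm_forward(X, model)
        assert out.shape == (6, 7)
        assert np.all((out > 0) & (out < 1))

    def test_shape_mismatch(self):
        model = self._model([3, 7])
        with pytest.raises(ValueError, match="expects 3"):
            helm_forward(np.zeros((2, 4)), model)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs, 60 samples, mildly imbalanced."""
    ds = make_imbalanced(SynthSpec(n_min=20, n_maj=40, n_informative=4,
                                   n_redundant=0, n_noise=0,
                                   class_separation=8.0, seed=11))
    return ds


class TestPGMELM:
    def test_separable_training_gmean(self, blobs):
        # weak regularization: this is a pure interpolation sanity bound
        model = pgmelm_fit(blobs.X, blobs.y, P=10, Q=2, C=1e4, seed=0)
        _, y_hat = predict(model, blobs.X)
        cm = confusion(blobs.y, y_hat)
        from pgmelm import classification_report
        assert classification_report(cm).g_mean >= 0.95

    def test_seed_determinism_and_layer_count(self, blobs):
        m1 = pgmelm_fit(blobs.X, blobs.y, P=6, Q=3, seed=42)
        m2 = pgmelm_fit(blobs.X, blobs.y, P=6, Q=3, seed=42)
        assert len(m1.layers) == 3 + 1
        for l1, l2 in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(l1.beta, l2.beta)

    def test_q1_equals_single_ae_plus_elm(self, blobs):
        # the num=1 / dIR=0 degenerate case is one ELM-AE layer + ELM
        X, y = blobs.X, blobs.y
        model = pgmelm_fit(X, y, P=5, Q=1, C=2.0, seed=7)
        rng = np.random.default_rng(7)
        beta_ae = elm_ae_fit(X, 5, l1=1e-3, iters=50,
                             seed=int(rng.integers(2**31 - 1)))
        H1 = sigmoid(X @ beta_ae.T)
        a, b = orthogonal_random_weights(5, 5, rng)
        H = sigmoid(H1 @ a + b)
        beta = elm_solve(H, y.astype(float)[:, None], 2.0)
        np.testing.assert_allclose(model.decision_layer.beta, beta, atol=1e-12)

    def test_invalid_structure(self, blobs):
        with pytest.raises(ValueError):
            pgmelm_fit(blobs.X, blobs.y, P=0, Q=1)


class TestWELM:
    def test_uniform_weights_rescale_regularizer(self):
        # balanced classes give W = (1/n_c) I, identical to plain ELM with
        # the regularizer scaled by that constant
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 6))
        y = np.array([0, 1] * 10)
        w = welm_fit(X, y, nodes=5, C=2.0, seed=4)
        H = sigmoid(X @ w.a + w.b)
        beta_plain = elm_solve(H, y.astype(float)[:, None], C=2.0 / 10)
        np.testing.assert_allclose(w.beta, beta_plain, atol=1e-10)

    def test_minority_tpr_at_least_plain_elm(self):
        # 1:9 skewed separable data: class weighting should not hurt recall
        diffs = []
        for seed in range(5):
            ds = make_imbalanced(SynthSpec(n_min=20, n_maj=180,
                                           class_separation=6.0, seed=seed))
            tr, te = split(ds, 100, seed=seed)
            mu, sd = tr.X.mean(0), tr.X.std(0, ddof=1)
            Xtr, Xte = (tr.X - mu) / sd, (te.X - mu) / sd
            def tpr(model):
                _, y_hat = predict(model, Xte)
                cm = confusion(te.y, y_hat)
                return cm.tp / (cm.tp + cm.fn)
            diffs.append(tpr(welm_fit(Xtr, tr.y, 10, seed=seed))
                         - tpr(elm_fit(Xtr, tr.y, 10, seed=seed)))
        assert np.median(diffs) >= 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            welm_fit(np.zeros((4, 2)), np.ones(4), nodes=2)


class TestPredictAndSerialize:
    def test_threshold_consistency_and_finiteness(self, blobs):
        model = elm_fit(blobs.X, blobs.y, nodes=8, seed=1)
        scores, labels = predict(model, np.zeros((1, blobs.X.shape[1])))
        assert np.isfinite(scores).all()
        np.testing.assert_array_equal(labels, (scores >= 0.5).astype(int))

    def test_roundtrip_bit_exact(self, blobs, tmp_path):
        for model in (pgmelm_fit(blobs.X, blobs.y, P=4, Q=2, seed=3),
                      welm_fit(blobs.X, blobs.y, nodes=6, seed=3)):
            path = tmp_path / "model.json"
            save_model(model, path)
            loaded = load_model(path)
            s1, l1 = predict(model, blobs.X)
            s2, l2 = predict(loaded, blobs.X)
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(l1, l2)

    def test_dimension_mismatch(self, blobs):
        model = elm_fit(blobs.X, blobs.y, nodes=8, seed=1)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, blobs.X.shape[1] + 1)))


def test_orthogonal_weights_structure():
    rng = np.random.default_rng(0)
    a, b = orthogonal_random_weights(6, 4, rng)
    np.testing.assert_allclose(a.T @ a, np.eye(4), atol=1e-10)
    a2, _ = orthogonal_random_weights(3, 8, rng)  # wide: orthonormal rows
    np.testing.assert_allclose(a2 @ a2.T, np.eye(3), atol=1e-10)
    assert np.linalg.norm(b) == pytest.approx(1.0)
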