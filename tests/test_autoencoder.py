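"""Sparse autoencoder: forward pass, cost, analytic gradients versus central
differences, sparsity pressure, greedy stacking, softmax head, fine-tuning
and model serialization."""

import numpy as np
import pytest

from ehgkit.autoencoder import (
    SAEHyperParams,
    SAEParams,
    SSAEModel,
    decode,
    encode,
    fine_tune,
    init_sae,
    kl_divergence,
    pretrain_stack,
    sae_cost,
    sae_gradient,
    sigmoid,
    softmax_probs,
    train_sae,
    train_softmax,
    train_ssae,
)


def _zero_params(n_in=4, n_hidden=3, **hyper):
    return SAEParams(
        W1=np.zeros((n_hidden, n_in)),
        b1=np.zeros(n_hidden),
        W2=np.zeros((n_in, n_hidden)),
        b2=np.zeros(n_in),
        hyper=SAEHyperParams(**hyper),
    )


class TestForwardPass:
    def test_zero_parameters_encode_to_half(self):
        p = _zero_params()
        Z = encode(p, np.random.default_rng(0).uniform(size=(4, 5)))
        np.testing.assert_array_equal(Z, np.full((3, 5), 0.5))

    def test_large_bias_saturates(self):
        p = _zero_params()
        p.b1[:] = 30.0
        Z = encode(p, np.zeros((4, 2)))
        assert np.all(Z > 1 - 1e-12)

    def test_single_unit_hand_value(self):
        p = SAEParams(W1=np.array([[1.0]]), b1=np.zeros(1),
                      W2=np.array([[1.0]]), b2=np.zeros(1))
        Z = encode(p, np.array([[1.0]]))
        assert Z[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert Z[0, 0] == pytest.approx(0.73106, abs=1e-5)
        h = decode(p, Z)
        assert h[0, 0] == pytest.approx(sigmoid(np.array([Z[0, 0]]))[0], abs=1e-15)

    def test_shape_mismatch_rejected(self):
        p = _zero_params(n_in=4, n_hidden=3)
        with pytest.raises(ValueError, match="expected 4 rows"):
            encode(p, np.zeros((5, 2)))
        with pytest.raises(ValueError, match="expected 3 rows"):
            decode(p, np.zeros((4, 2)))


class TestKLDivergence:
    def test_identity_is_zero(self):
        assert kl_divergence(0.05, 0.05) == 0.0

    def test_hand_evaluated_value(self):
        # 0.05 ln(0.5) + 0.95 ln(0.95/0.90)
        expected = 0.05 * np.log(0.05 / 0.10) + 0.95 * np.log(0.95 / 0.90)
        assert kl_divergence(0.05, 0.10) == pytest.approx(expected, abs=1e-15)
        assert kl_divergence(0.05, 0.10) == pytest.approx(0.0167065, abs=1e-6)

    def test_positive_off_diagonal(self):
        grid = [0.01, 0.05, 0.2, 0.5, 0.9]
        for rho in grid:
            for rho_hat in grid:
                val = kl_divergence(rho, rho_hat)
                assert val >= 0
                if rho != rho_hat:
                    assert val > 0

    def test_extreme_arguments_clamped_not_nan(self):
        assert np.isfinite(kl_divergence(0.05, 0.0))
        assert np.isfinite(kl_divergence(0.05, 1.0))


class TestCost:
    def test_zero_weights_closed_form(self):
        """With all parameters zero the reconstruction is 0.5 everywhere, so
        the data term is (1/N) sum_i 0.5 ||0.5 - x_i||^2."""
        p = _zero_params(n_in=2, n_hidden=3, beta=0.0, lambda_=0.0)
        X = np.array([[0.0, 1.0], [0.5, 0.25]])  # 2 features x 2 samples
        expected = 0.5 * (
            ((0.5 - 0.0) ** 2 + (0.5 - 0.5) ** 2)
            + ((0.5 - 1.0) ** 2 + (0.5 - 0.25) ** 2)
        ) / 2
        cost, rho_hat = sae_cost(p, X)
        assert cost == pytest.approx(expected, abs=1e-15)
        np.testing.assert_array_equal(rho_hat, np.full(3, 0.5))

    def test_sparsity_term_at_half_activation(self):
        p = _zero_params(n_in=2, n_hidden=3, beta=1.0, rho=0.05, lambda_=0.0)
        X = np.full((2, 4), 0.5)
        cost, _ = sae_cost(p, X)
        kl_half = 0.05 * np.log(0.1) + 0.95 * np.log(1.9)
        assert kl_half == pytest.approx(0.49463, abs=1e-5)
        recon = 0.0  # reconstruction of 0.5 inputs is exact at zero weights
        assert cost == pytest.approx(recon + 3 * kl_half, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("beta,lambda_", [(0.0, 0.0), (3.0, 0.01), (8.0, 0.001)])
    def test_matches_central_differences(self, beta, lambda_):
        rng = np.random.default_rng(3)
        hyper = SAEHyperParams(rho=0.05, beta=beta, lambda_=lambda_)
        p = init_sae(5, 3, rng, hyper)
        X = rng.uniform(0, 1, size=(5, 7))
        g = sae_gradient(p, X)
        eps = 1e-5
        for name in ("W1", "b1", "W2", "b2"):
            arr = getattr(p, name)
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                jp, _ = sae_cost(p, X)
                arr[idx] = orig - eps
                jm, _ = sae_cost(p, X)
                arr[idx] = orig
                num[idx] = (jp - jm) / (2 * eps)
            rel = np.max(np.abs(num - g[name]) / (np.abs(num) + 1e-8))
            assert rel < 1e-6, f"{name} gradient off by {rel}"

    def test_weight_decay_only_at_fixed_point(self):
        """At X = 0.5 (the zero-parameter reconstruction fixed point) with
        beta = 0, the only surviving gradient is the decay term lambda W."""
        rng = np.random.default_rng(5)
        p = _zero_params(n_in=3, n_hidden=2, beta=0.0, lambda_=0.1)
        p.W1 = rng.standard_normal((2, 3))  # W2 = 0 keeps reconstruction at 0.5
        X = np.full((3, 4), 0.5)
        g = sae_gradient(p, X)
        np.testing.assert_allclose(g["W1"], 0.1 * p.W1, atol=1e-12)
        np.testing.assert_allclose(g["W2"], 0.1 * p.W2, atol=1e-12)
        np.testing.assert_allclose(g["b2"], np.zeros(3), atol=1e-12)


@pytest.fixture(scope="module")
def latent_data():
    rng = np.random.default_rng(7)
    z = rng.uniform(0, 1, size=200)  # 1-D latent structure in 10-D
    basis = rng.uniform(-1, 1, size=(10,))
    return sigmoid(np.outer(basis, z) + 0.05 * rng.standard_normal((10, 200)))


class TestTraining:
    def test_loss_halves_on_structured_data(self, latent_data):
        hyper = SAEHyperParams(beta=0.5, lambda_=1e-4, epsilon=0.5, epochs=300)
        _, history = train_sae(latent_data, 4, hyper, seed=0)
        assert history[-1] < history[0] / 2

    def test_trailing_loss_decreases(self, latent_data):
        hyper = SAEHyperParams(beta=0.5, lambda_=1e-4, epsilon=0.5, epochs=200)
        _, history = train_sae(latent_data, 4, hyper, seed=0)
        h = np.asarray(history)
        assert h[-20:].mean() < h[:20].mean()

    def test_deterministic_given_seed(self, latent_data):
        hyper = SAEHyperParams(epochs=30)
        p1, h1 = train_sae(latent_data, 4, hyper, seed=3)
        p2, h2 = train_sae(latent_data, 4, hyper, seed=3)
        np.testing.assert_array_equal(p1.W1, p2.W1)
        np.testing.assert_array_equal(p1.b2, p2.b2)
        assert h1 == h2

    def test_sparsity_pressure_drives_activations_toward_rho(self, latent_data):
        sparse = SAEHyperParams(beta=50.0, rho=0.05, epochs=200)
        loose = SAEHyperParams(beta=0.0, rho=0.05, epochs=200)
        p_s, _ = train_sae(latent_data, 4, sparse, seed=1)
        p_l, _ = train_sae(latent_data, 4, loose, seed=1)
        _, rho_s = sae_cost(p_s, latent_data)
        _, rho_l = sae_cost(p_l, latent_data)
        assert abs(rho_s.mean() - 0.05) < abs(rho_l.mean() - 0.05)


class TestStack:
    def test_layer_shapes_and_chaining(self, rng):
        X = rng.uniform(0, 1, size=(64, 40))
        hyper = SAEHyperParams(epochs=5)
        layers, _ = pretrain_stack(X, (30, 10), hyper, seed=0)
        assert layers[0].W1.shape == (30, 64)
        assert layers[1].W1.shape == (10, 30)

    def test_second_layer_sees_first_layer_codes(self, rng):
        X = rng.uniform(0, 1, size=(8, 30))
        hyper = SAEHyperParams(epochs=5)
        layers, _ = pretrain_stack(X, (4, 2), hyper, seed=0)
        # retraining layer 2 on encode(layer1, X) reproduces it exactly
        Z1 = encode(layers[0], X)
        p2, _ = train_sae(Z1, 2, hyper, seed=1)
        np.testing.assert_array_equal(p2.W1, layers[1].W1)

    def test_deterministic(self, rng):
        X = rng.uniform(0, 1, size=(8, 30))
        hyper = SAEHyperParams(epochs=5)
        a, _ = pretrain_stack(X, (4, 2), hyper, seed=9)
        b, _ = pretrain_stack(X, (4, 2), hyper, seed=9)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.W1, lb.W1)


class TestSoftmaxHead:
    def test_zero_logits_are_uniform(self):
        P = softmax_probs(np.zeros((2, 3)), np.zeros(2), np.ones((3, 4)))
        np.testing.assert_allclose(P, 0.5)

    def test_columns_sum_to_one(self, rng):
        P = softmax_probs(rng.standard_normal((2, 5)), rng.standard_normal(2),
                          rng.uniform(size=(5, 9)))
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)

    def test_saturation(self):
        W = np.array([[1.0], [-1.0]])
        P = softmax_probs(W, np.zeros(2), np.array([[500.0]]))
        np.testing.assert_allclose(P[:, 0], [1.0, 0.0], atol=1e-100)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            train_softmax(np.ones((3, 4)), np.array([0, 1, 2, 1]))


class TestFineTuning:
    def _toy_problem(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.uniform(0, 1, size=(6, n)) * 0.2
        X[:3, y == 1] += 0.6  # separable blocks
        return np.clip(X, 0, 1), y

    def test_fine_tuning_lowers_training_cross_entropy(self):
        X, y = self._toy_problem()
        frozen = train_ssae(X.T, y, hidden_sizes=(4, 3),
                            hyper=SAEHyperParams(epochs=50),
                            do_fine_tune=False, seed=0)
        tuned = train_ssae(X.T, y, hidden_sizes=(4, 3),
                           hyper=SAEHyperParams(epochs=50),
                           fine_tune_epochs=150, seed=0)
        assert tuned.training_log["fine_tune_train"][-1] < \
            frozen.training_log["softmax"][-1]

    def test_end_to_end_separable_accuracy(self):
        X, y = self._toy_problem()
        model = train_ssae(X.T, y, hidden_sizes=(4, 3),
                           hyper=SAEHyperParams(epochs=100),
                           fine_tune_epochs=200, seed=1)
        assert np.mean(model.predict(X.T) == y) >= 0.95

    def test_probabilities_sum_to_one(self):
        X, y = self._toy_problem()
        model = train_ssae(X.T, y, hidden_sizes=(4, 3),
                           hyper=SAEHyperParams(epochs=20), seed=0)
        np.testing.assert_allclose(model.predict_proba(X.T).sum(axis=1), 1.0,
                                   atol=1e-12)


class TestSerialization:
    def test_json_round_trip_is_bitwise(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(6, 30))
        y = np.repeat([0, 1], 15)
        model = train_ssae(X.T, y, hidden_sizes=(4, 2),
                           hyper=SAEHyperParams(epochs=10),
                           fine_tune_epochs=10, seed=0)
        model.to_json(tmp_path / "m.json")
        back = SSAEModel.from_json(tmp_path / "m.json")
        for la, lb in zip(model.layers, back.layers):
            np.testing.assert_array_equal(la.W1, lb.W1)
            np.testing.assert_array_equal(la.W2, lb.W2)
        np.testing.assert_array_equal(model.softmax_W, back.softmax_W)
        np.testing.assert_array_equal(
            model.predict_proba(X.T), back.predict_proba(X.T)
        )

    def test_wrong_format_rejected(self, tmp_path):
        (tmp_path / "x.json").write_text('{"format": "other"}')
        with pytest.raises(ValueError, match="bundle"):
            SSAEModel.from_json(tmp_path / "x.json")


class TestDivergenceGuard:
    def test_nan_cost_aborts_with_diagnostic(self):
        X = np.random.default_rng(0).uniform(size=(4, 10))
        # absurd learning rate forces overflow/divergence
        hyper = SAEHyperParams(epsilon=1e6, epochs=200, beta=8.0)
        with pytest.raises(FloatingPointError, match="diverged"):
            with np.errstate(over="ignore", invalid="ignore"):
                train_sae(X, 3, hyper, seed=0)
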