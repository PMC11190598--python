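import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emghht import (
    DivergedTrainingError,
    NetworkParams,
    TrainConfig,
    ValidationError,
    forward,
    lrelu,
    predict,
    softmax,
    train,
)
from emghht.dnn import init_params, load_params, loss_and_grads, save_params


def gaussian_clouds(n=200, seed=0):
    """Two well-separated Gaussian feature clouds, the training fixture."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(-2.0, 0.5, size=(n // 2, 4)), rng.normal(2.0, 0.5, size=(n // 2, 4))]
    )
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(5.0, 5.0), (0.0, 0.0), (-2.0, -0.02)])
    def test_leaky_relu_branches(self, x, expected):
        assert lrelu(x) == pytest.approx(expected, abs=1e-15)

    def test_softmax_uniform_on_equal_logits(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3, rtol=1e-12)

    def test_softmax_hand_evaluated(self):
        np.testing.assert_allclose(softmax([np.log(2.0), 0.0]), [2 / 3, 1 / 3], rtol=1e-12)

    @given(
        logits=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
        shift=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_softmax_is_a_shift_invariant_distribution(self, logits, shift):
        p = softmax(logits)
        assert abs(p.sum() - 1.0) <= 1e-12
        assert np.all(p >= 0) and np.all(p <= 1)  # saturates in float at extreme gaps
        np.testing.assert_allclose(softmax(np.array(logits) + shift), p, rtol=1e-9)


class TestForward:
    def test_zero_network_outputs_uniform(self):
        params = init_params([4, 8, 3], seed=0)
        for w in params.weights:
            w[:] = 0.0
        np.testing.assert_allclose(forward(params, np.ones(4)), 1 / 3, rtol=1e-12)

    def test_single_layer_identity_reduces_to_softmax(self):
        params = init_params([3, 3], seed=0)
        params.weights[0][:] = np.eye(3)
        params.biases[0][:] = 0.0
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(forward(params, x), softmax(x), rtol=1e-12)

    def test_matches_independent_forward_pass(self):
        """Duplicate-implementation oracle for a random 3-layer net."""
        rng = np.random.default_rng(7)
        params = init_params([5, 7, 6, 4], seed=7)
        x = rng.standard_normal(5)
        a = x
        for i, (w, b) in enumerate(zip(params.weights, params.biases)):
            z = w @ a + b
            if i < len(params.weights) - 1:
                a = np.where(z > 0, z, 0.01 * z)
            else:
                e = np.exp(z - z.max())
                a = e / e.sum()
        np.testing.assert_allclose(forward(params, x), a, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        params = init_params([4, 3], seed=0)
        with pytest.raises(ValidationError):
            forward(params, np.ones(5))


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Analytic gradients agree with numeric ones to 1e-5 relative."""
        rng = np.random.default_rng(3)
        params = init_params([4, 6, 5, 3], seed=3)
        X = rng.standard_normal((10, 4))
        y = rng.integers(0, 3, size=10)
        _, grads_w, grads_b = loss_and_grads(params, X, y)
        eps = 1e-6
        for layer in range(len(params.weights)):
            for arr, grads in ((params.weights, grads_w), (params.biases, grads_b)):
                flat = arr[layer].ravel()
                gflat = grads[layer].ravel()
                for idx in range(0, flat.size, max(flat.size // 10, 1)):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp, _, _ = loss_and_grads(params, X, y)
                    flat[idx] = orig - eps
                    lm, _, _ = loss_and_grads(params, X, y)
                    flat[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    denom = max(abs(numeric), abs(gflat[idx]), 1e-8)
                    assert abs(numeric - gflat[idx]) / denom <= 1e-5


class TestTraining:
    def test_separable_clouds_reach_high_training_accuracy(self):
        X, y = gaussian_clouds()
        params = train(X, y, config=TrainConfig(seed=1))
        pred, _ = predict(params, X)
        assert np.mean(pred == y) >= 0.95

    def test_full_batch_loss_is_non_increasing(self):
        X, y = gaussian_clouds(n=60, seed=2)
        params = train(
            X, y, config=TrainConfig(learning_rate=0.005, epochs=50, batch_size=60, seed=2)
        )
        losses = np.array(params.loss_history)
        assert np.all(np.diff(losses) <= 1e-6)

    def test_same_seed_reproduces_weights_exactly(self):
        X, y = gaussian_clouds(n=80, seed=4)
        cfg = TrainConfig(epochs=20, seed=9)
        a = train(X, y, config=cfg)
        b = train(X, y, config=cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValidationError, match="2 classes"):
            train(X, np.zeros(10, dtype=int))

    def test_divergence_names_learning_rate(self):
        X, y = gaussian_clouds(n=40, seed=5)
        with pytest.raises(DivergedTrainingError, match="learning_rate"):
            train(
                X,
                y,
                config=TrainConfig(
                    learning_rate=1e30, epochs=50, standardize_features=False, seed=5
                ),
            )


class TestPredict:
    def test_uniform_probabilities_break_ties_to_lowest_index(self):
        params = init_params([4, 3], seed=0)
        for w in params.weights:
            w[:] = 0.0
        label, probs = predict(params, np.ones(4))
        assert label == 0
        np.testing.assert_allclose(probs, 1 / 3, rtol=1e-12)

    def test_probabilities_are_the_forward_output(self):
        params = init_params([4, 5, 3], seed=2)
        x = np.arange(4.0)
        _, probs = predict(params, x)
        np.testing.assert_array_equal(probs, forward(params, x))

    def test_round_trip_serialization(self, tmp_path):
        X, y = gaussian_clouds(n=60, seed=6)
        params = train(X, y, config=TrainConfig(epochs=10, seed=6))
        save_params(params, tmp_path / "model.npz")
        loaded = load_params(tmp_path / "model.npz")
        np.testing.assert_array_equal(forward(loaded, X[0]), forward(params, X[0]))
        assert loaded.layer_sizes == params.layer_sizes
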