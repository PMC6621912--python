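"""Oracle tests for the two-stage attention readout.

The forward pass is checked against hand-computed softmax/sigmoid
values on a printed fixture; the analytic gradients are checked against
central finite differences at 1e-5 relative tolerance.
"""

import numpy as np
import pytest

from deeplsm.attention_readout import (
    AttentionParams,
    collapse_layers,
    deep_attention,
    loss_and_gradients,
    predict,
    readout,
    spatial_attention,
    train_readout,
)

SOFTMAX_100 = np.array([0.5761168847658291, 0.21194155761708544,
                        0.21194155761708544])  # softmax([1, 0, 0])
SIGMOID_2 = 0.8807970779778823
SIGMOID_HALF = 0.6224593312018546
SIGMOID_1 = 0.7310585786300049


class TestStages:
    def test_deep_attention_hand_values(self):
        # L = 3, N = 1: identity logits -> softmax([1, 0, 0])
        a = deep_attention(np.array([1.0, 0.0, 0.0]), np.eye(3))
        assert np.allclose(a, SOFTMAX_100, atol=1e-12)

    def test_deep_attention_is_distribution(self):
        rng = np.random.default_rng(0)
        a = deep_attention(rng.random(6), rng.standard_normal((2, 6)))
        assert a.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((a > 0) & (a < 1))

    def test_deep_attention_shift_invariant(self):
        x = np.array([0.3, 0.7, 0.1])
        w = np.vstack([np.eye(3)[0], np.eye(3)[1], np.eye(3)[2]])
        a = deep_attention(x, w)
        b = deep_attention(x, w + 5.0)  # shifts every logit by 5 * sum(x)
        assert np.allclose(a, b, atol=1e-12)

    def test_collapse_hand_value(self):
        xs = collapse_layers(np.array([1.0, 2.0, 3.0]),
                             np.array([0.2, 0.3, 0.5]))
        assert xs[0] == pytest.approx(2.3, abs=1e-12)

    def test_spatial_attention_hand_value(self):
        g = spatial_attention(np.array([2.0]), np.array([[1.0]]))
        assert g[0] == pytest.approx(SIGMOID_2, abs=1e-12)

    def test_fan_in_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deep_attention(np.zeros(5), np.zeros((2, 6)))


class TestReadoutFixture:
    """Hand-computed forward pass: L = 2, N = 3, O = 2, no standardization.

    x = [1,0,0 | 0,1,0]; w_deep row 0 picks x[0] -> logits [1, 0] ->
    A = [s(1), 1 - s(1)]; zero spatial logits -> gates 0.5; w_out row 0 =
    ones -> z0 = 0.5 * (A0 + A1) = 0.5 -> y = [s(0.5), 0.5].
    """

    def params(self):
        w_deep = np.zeros((2, 6))
        w_deep[0, 0] = 1.0
        return AttentionParams(
            w_deep=w_deep,
            w_spatial=np.zeros((3, 6)),
            w_out=np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]]),
        )

    def test_forward_hand_values(self):
        x = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        y, label = readout(x, self.params())
        assert y[0] == pytest.approx(SIGMOID_HALF, abs=1e-12)
        assert y[1] == pytest.approx(0.5, abs=1e-12)
        assert label == 0

    def test_intermediate_attention_values(self):
        x = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        p = self.params()
        a = deep_attention(x, p.w_deep)
        assert a[0] == pytest.approx(SIGMOID_1, abs=1e-12)
        xs = collapse_layers(x, a)
        assert np.allclose(xs, [SIGMOID_1, 1 - SIGMOID_1, 0.0], atol=1e-12)

    def test_uniform_scores_give_log_o_loss(self):
        # all-zero weights -> y = 0.5 everywhere -> softmax uniform
        p = AttentionParams(w_deep=np.zeros((2, 6)),
                            w_spatial=np.zeros((3, 6)),
                            w_out=np.zeros((3, 3)))
        loss, _ = loss_and_gradients(p, np.random.default_rng(0).random((4, 6)),
                                     np.array([0, 1, 2, 0]))
        assert loss == pytest.approx(np.log(3.0), abs=1e-12)


class TestGradients:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(1)
        params = AttentionParams.create(2, 3, 2, seed=2, init_scale=0.5)
        X = rng.random((5, 6))
        y = np.array([0, 1, 0, 1, 1])
        _, grads = loss_and_gradients(params, X, y)
        eps = 1e-5
        for name in ("w_deep", "w_spatial", "w_out"):
            w = getattr(params, name)
            numeric = np.zeros_like(w)
            for idx in np.ndindex(w.shape):
                orig = w[idx]
                w[idx] = orig + eps
                lp, _ = loss_and_gradients(params, X, y)
                w[idx] = orig - eps
                lm, _ = loss_and_gradients(params, X, y)
                w[idx] = orig
                numeric[idx] = (lp - lm) / (2 * eps)
            denom = np.maximum(np.abs(numeric) + np.abs(grads[name]), 1e-4)
            assert np.max(np.abs(numeric - grads[name]) / denom) < 1e-5, name


class TestTraining:
    def separable_snapshots(self, n_per_class=10, n_classes=3, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for c in range(n_classes):
            block = rng.normal(0, 0.05, (n_per_class, 2 * 6))
            block[:, c] += 3.0  # layer-1 channel c carries the class
            X.append(block)
            y.extend([c] * n_per_class)
        return np.concatenate(X), np.array(y)

    def test_loss_decreases_and_fits_separable_data(self):
        X, y = self.separable_snapshots()
        params, losses = train_readout(X, y, n_layers=2, lr=0.5, epochs=500,
                                       seed=0)
        assert losses[-1] < losses[0]
        # full-batch descent at this step size is monotone on this problem
        assert np.all(np.diff(losses) < 1e-8)
        acc = float(np.mean(predict(X, params) == y))
        assert acc >= 0.95

    def test_zero_learning_rate_changes_nothing(self):
        X, y = self.separable_snapshots()
        init = AttentionParams.create(2, 6, 3, seed=1)
        params, _ = train_readout(X, y, n_layers=2, lr=0.0, epochs=5, seed=1)
        for name in ("w_deep", "w_spatial", "w_out"):
            assert np.array_equal(getattr(params, name), getattr(init, name))

    def test_deterministic_under_seed(self):
        X, y = self.separable_snapshots()
        a, _ = train_readout(X, y, n_layers=2, lr=0.2, epochs=50, seed=3)
        b, _ = train_readout(X, y, n_layers=2, lr=0.2, epochs=50, seed=3)
        assert np.array_equal(a.w_out, b.w_out)

    def test_global_standardization_is_scalar(self):
        X, y = self.separable_snapshots()
        params, _ = train_readout(X, y, n_layers=2, lr=0.2, epochs=10, seed=0)
        assert np.all(params.mean == params.mean[0])
        assert np.all(params.scale == params.scale[0])
        assert params.mean[0] == pytest.approx(X.mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_readout(np.random.default_rng(0).random((4, 6)),
                          np.zeros(4, dtype=int), n_layers=2)

    def test_indivisible_snapshot_length_rejected(self):
        with pytest.raises(ValueError):
            train_readout(np.zeros((4, 7)), np.array([0, 1, 0, 1]),
                          n_layers=2)


class TestPredictNoise:
    def test_zero_sigma_bit_identical(self):
        X, y = TestTraining().separable_snapshots()
        params, _ = train_readout(X, y, n_layers=2, lr=0.5, epochs=100, seed=0)
        clean = predict(X, params)
        assert np.array_equal(predict(X, params, noise_sigma=0.0), clean)

    def test_read_noise_is_seeded(self):
        X, y = TestTraining().separable_snapshots()
        params, _ = train_readout(X, y, n_layers=2, lr=0.5, epochs=100, seed=0)
        a = predict(X, params, noise_sigma=0.05, noise_seed=1)
        b = predict(X, params, noise_sigma=0.05, noise_seed=1)
        assert np.array_equal(a, b)
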