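"""Tests of the from-scratch 1-D CNN: forward pass, backprop, training rules."""

import numpy as np
import pytest

from mieeg.cnn import (
    CNNArchitecture,
    ConvSpec,
    TrainingConfig,
    backward,
    conv_forward,
    dense_forward,
    dropout_mask,
    forward,
    init_parameters,
    lr_at,
    one_hot,
    pool_backward,
    pool_forward,
    predict,
    sgd_step,
    sse_loss,
)


def naive_conv(x, kernels, bias):
    """Literal triple-sum valid convolution with ReLU (independent oracle)."""
    n_k, depth, k_len = kernels.shape
    out_len = x.shape[1] - k_len + 1
    out = np.zeros((n_k, out_len))
    for i in range(n_k):
        for j in range(out_len):
            acc = bias[i]
            for d in range(depth):
                for n in range(k_len):
                    acc += kernels[i, d, n] * x[d, j + n]
            out[i, j] = max(acc, 0.0)
    return out


def numeric_gradient(params, arch, x, targets, h=1e-6):
    """Central finite differences of the batch-mean SSE loss."""
    grads = []
    for a in params._arrays():
        g = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = a[idx]
            a[idx] = orig + h
            lp = sse_loss(forward(params, arch, x).probs, targets)
            a[idx] = orig - h
            lm = sse_loss(forward(params, arch, x).probs, targets)
            a[idx] = orig
            g[idx] = (lp - lm) / (2.0 * h)
        grads.append(g.ravel())
    return np.concatenate(grads)


class TestInitParameters:
    ARCH = CNNArchitecture(input_length=4)

    def test_conv_kernels_bounded(self):
        for seed in range(10):
            params = init_parameters(self.ARCH, seed)
            for k in params.conv_kernels:
                assert np.max(np.abs(k)) <= 0.3

    def test_dense_weights_bounded(self):
        params = init_parameters(self.ARCH, 0)
        assert np.max(np.abs(params.dense_w)) <= 0.3
        assert np.max(np.abs(params.out_w)) <= 0.3

    def test_all_biases_are_tenth(self):
        params = init_parameters(self.ARCH, 5)
        for b in params.conv_biases:
            assert np.all(b == 0.1)
        assert np.all(params.dense_b == 0.1)
        assert np.all(params.out_b == 0.1)

    def test_same_seed_identical(self):
        a = init_parameters(self.ARCH, 9)
        b = init_parameters(self.ARCH, 9)
        assert np.array_equal(a.flatten(), b.flatten())

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            CNNArchitecture(input_length=4, conv_layers=(ConvSpec(8, 3), ConvSpec(16, 3)))
        with pytest.raises(ValueError):
            CNNArchitecture(input_length=4, n_classes=3)


class TestConvForward:
    def test_simple_example(self):
        act, _ = conv_forward(np.array([[1.0, 2.0, 3.0]]),
                              np.array([[[1.0, 1.0]]]), np.zeros(1))
        assert np.array_equal(act, [[3.0, 5.0]])

    def test_relu_clamps_negative(self):
        act, net = conv_forward(np.array([[1.0, -2.0, 3.0]]),
                                np.array([[[1.0, 0.0]]]), np.zeros(1))
        assert np.array_equal(act, [[1.0, 0.0]])
        assert np.array_equal(net, [[1.0, -2.0]])

    def test_depth_linearity(self, rng):
        """A depth-2 convolution is the sum of the per-depth convolutions."""
        x = rng.normal(size=(2, 8))
        k = rng.normal(size=(3, 2, 3))
        bias = np.zeros(3)
        _, net_both = conv_forward(x, k, bias)
        _, net_0 = conv_forward(x[:1], k[:, :1], bias)
        _, net_1 = conv_forward(x[1:], k[:, 1:], bias)
        assert np.allclose(net_both, net_0 + net_1, atol=1e-12)

    def test_matches_triple_sum_oracle(self, rng):
        for _ in range(10):
            depth = int(rng.integers(1, 4))
            length = int(rng.integers(4, 10))
            k_len = int(rng.integers(1, min(4, length) + 1))
            x = rng.normal(size=(depth, length))
            k = rng.normal(size=(int(rng.integers(1, 4)), depth, k_len))
            bias = rng.normal(size=k.shape[0])
            act, _ = conv_forward(x, k, bias)
            assert np.allclose(act, naive_conv(x, k, bias), atol=1e-12)

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv_forward(np.ones((1, 2)), np.ones((1, 1, 3)), np.zeros(1))


class TestDenseForward:
    def test_zero_input_zero_bias_tanh(self):
        out = dense_forward(np.zeros(3), np.ones((3, 2)), np.zeros(2), "tanh")
        assert np.array_equal(out, np.zeros(2))

    def test_softmax_symmetry(self):
        out = dense_forward(np.zeros(2), np.zeros((2, 2)), np.zeros(2), "softmax")
        assert np.allclose(out, [0.5, 0.5])

    def test_scalar_tanh_value(self):
        out = dense_forward(np.array([0.5]), np.array([[1.0]]), np.zeros(1))
        assert out[0] == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert out[0] == pytest.approx(0.4621, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dense_forward(np.zeros(3), np.ones((4, 2)), np.zeros(2))


class TestSseLoss:
    def test_perfect_prediction(self):
        assert sse_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0])) == 0.0

    def test_half_half_against_one_hot(self):
        assert sse_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(0.5)

    def test_nonnegative(self, rng):
        for _ in range(20):
            y = rng.random(2)
            r = one_hot([int(rng.integers(0, 2))])[0]
            assert sse_loss(y, r) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sse_loss(np.zeros(2), np.zeros(3))


class TestBackward:
    def test_gradients_match_finite_differences(self):
        """The module's primary contract: analytic backprop equals central
        finite differences (rel err < 1e-5) on >=20 random small nets."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n_in = int(rng.integers(4, 13))
            k1 = int(rng.integers(1, min(4, n_in) + 1))
            l1 = n_in - k1 + 1
            k2 = int(rng.integers(1, min(4, l1) + 1))
            arch = CNNArchitecture(
                input_length=n_in,
                conv_layers=(ConvSpec(int(rng.integers(1, 4)), k1),
                             ConvSpec(int(rng.integers(1, 4)), k2)),
                dense_width=int(rng.integers(1, 4)),
            )
            params = init_parameters(arch, int(rng.integers(0, 2 ** 16)))
            x = rng.normal(size=(3, n_in))
            targets = one_hot(rng.integers(0, 2, size=3))
            trace = forward(params, arch, x)
            analytic = backward(trace, params, arch, targets).flatten()
            numeric = numeric_gradient(params, arch, x, targets)
            diff = np.abs(analytic - numeric)
            rel = diff / np.maximum(np.abs(analytic) + np.abs(numeric), 1e-6)
            # below ~1e-9 absolute the central difference itself is round-off
            assert np.all((rel < 1e-5) | (diff < 1e-9))

    def test_zero_delta_gives_zero_gradients(self):
        """If the softmax output already equals the target at a symmetric
        construction, every gradient vanishes."""
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        x = np.zeros((1, 4))
        trace = forward(params, arch, x)
        grads = backward(trace, params, arch, trace.probs.copy())
        assert np.allclose(grads.flatten(), 0.0, atol=1e-12)

    def test_duplicate_sample_keeps_mean_gradient(self):
        """Batch-mean gradients: duplicating the batch leaves them unchanged,
        and summing per-sample gradients doubles a two-sample batch."""
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4))
        t = one_hot([1])
        g1 = backward(forward(params, arch, x), params, arch, t).flatten()
        x2, t2 = np.vstack([x, x]), np.vstack([t, t])
        g2 = backward(forward(params, arch, x2), params, arch, t2).flatten()
        assert np.allclose(g1, g2, atol=1e-12)


class TestPooling:
    def test_average_splits_delta_evenly(self):
        out, trace = pool_forward(np.array([[1.0, 3.0]]), 2, "average")
        assert np.array_equal(out, [[2.0]])
        back = pool_backward(np.array([[4.0]]), "average", trace)
        assert np.array_equal(back, [[2.0, 2.0]])

    def test_max_routes_delta_to_argmax(self):
        out, trace = pool_forward(np.array([[1.0, 7.0]]), 2, "max")
        assert np.array_equal(out, [[7.0]])
        back = pool_backward(np.array([[5.0]]), "max", trace)
        assert np.array_equal(back, [[0.0, 5.0]])

    def test_max_ties_go_to_lowest_index(self):
        _, trace = pool_forward(np.array([[2.0, 2.0]]), 2, "max")
        back = pool_backward(np.array([[1.0]]), "max", trace)
        assert np.array_equal(back, [[1.0, 0.0]])

    @pytest.mark.parametrize("mode", ["max", "average"])
    def test_delta_conservation(self, mode, rng):
        x = rng.normal(size=(2, 3, 8))
        _, trace = pool_forward(x, 2, mode)
        delta = rng.normal(size=(2, 3, 4))
        back = pool_backward(delta, mode, trace)
        assert back.sum() == pytest.approx(delta.sum(), abs=1e-10)


class TestDropout:
    def test_rate_zero_keeps_everything(self, rng):
        assert np.all(dropout_mask((5, 5), 0.0, rng) == 1.0)

    def test_keep_fraction_at_half(self):
        rng = np.random.default_rng(1)
        masks = dropout_mask((100000, 10), 0.5, rng)
        assert masks.mean() == pytest.approx(0.5, abs=0.005)

    def test_inference_is_deterministic(self):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        x = np.array([[0.3, -0.2, 0.1, 0.4]])
        p1 = forward(params, arch, x).probs
        p2 = forward(params, arch, x).probs
        assert np.array_equal(p1, p2)

    def test_inverted_dropout_preserves_expectation(self):
        """Mean activation with inverted dropout matches the deterministic
        activation within 3 SE over 1e4 draws."""
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 3)
        x = np.array([[0.5, -0.1, 0.2, 0.3]])
        det = forward(params, arch, x).dense_act[0]
        rng = np.random.default_rng(0)
        draws = np.stack([
            forward(params, arch, x, training=True, dropout_rate=0.5,
                    rng=rng).dense_out[0]
            for _ in range(10000)
        ])
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - det) < 3.5 * se + 1e-9)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            dropout_mask((2,), 1.0, rng)


class TestLearningRate:
    CFG = TrainingConfig()

    def test_initial_value(self):
        assert lr_at(0, self.CFG) == pytest.approx(0.02)

    def test_limit_value(self):
        assert lr_at(10 ** 6, self.CFG) == pytest.approx(0.0002, abs=1e-9)

    def test_closed_form_at_decay_speed(self):
        expected = 0.0002 + 0.0198 * np.exp(-1.0)
        assert lr_at(1000, self.CFG) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.007485, abs=1e-6)

    def test_monotone_decreasing(self):
        values = [lr_at(i, self.CFG) for i in range(0, 5000, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, self.CFG)


class TestSgdStep:
    def test_zero_gradient_keeps_parameters(self):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        zero = backward(forward(params, arch, np.zeros((1, 4))), params, arch,
                        forward(params, arch, np.zeros((1, 4))).probs)
        updated = sgd_step(params, zero, 0.1)
        assert np.allclose(updated.flatten(), params.flatten(), atol=1e-12)

    def test_scalar_arithmetic(self):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        grads = params.copy()
        updated = sgd_step(params, grads, 0.1)
        assert np.allclose(updated.flatten(), 0.9 * params.flatten(), atol=1e-12)

    def test_nonpositive_eta_rejected(self):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        with pytest.raises(ValueError):
            sgd_step(params, params, 0.0)


class TestPredictAndTraining:
    def test_probabilities_sum_to_one(self, rng):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        _, probs = predict(params, arch, rng.normal(size=(7, 4)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_feature_length_mismatch_rejected(self):
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        with pytest.raises(ValueError):
            predict(params, arch, np.zeros(5))

    def test_loss_decreases_on_separable_toy_set(self):
        """Full-batch loss is non-increasing (to 1e-9) over the first 50
        iterations on a linearly separable toy problem."""
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(loc=+1.0, size=(10, 4)),
                       rng.normal(loc=-1.0, size=(10, 4))])
        y = one_hot(np.array([0] * 10 + [1] * 10))
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 0)
        cfg = TrainingConfig()
        losses = []
        for i in range(50):
            trace = forward(params, arch, x)
            losses.append(sse_loss(trace.probs, y))
            grads = backward(trace, params, arch, y)
            params = sgd_step(params, grads, lr_at(i, cfg))
        diffs = np.diff(losses)
        assert np.all(diffs <= 1e-9)
        assert losses[-1] < losses[0]

    def test_overfits_four_toy_points(self):
        """A net trained to zero training error reproduces all 4 points."""
        x = np.array([[1.0, 0.0, 1.0, 0.0], [0.8, 0.1, 0.9, 0.0],
                      [0.0, 1.0, 0.0, 1.0], [0.1, 0.9, 0.0, 0.8]])
        labels = np.array([0, 0, 1, 1])
        y = one_hot(labels)
        arch = CNNArchitecture(input_length=4)
        params = init_parameters(arch, 1)
        cfg = TrainingConfig()
        for i in range(400):
            trace = forward(params, arch, x)
            grads = backward(trace, params, arch, y)
            params = sgd_step(params, grads, lr_at(i, cfg))
        pred, _ = predict(params, arch, x)
        assert np.array_equal(pred, labels)
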