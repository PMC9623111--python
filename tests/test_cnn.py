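"""Network operators vs brute-force oracles, training behaviour, persistence."""

import numpy as np
import pytest

from cottonfvfm.cnn import (
    CNNConfig,
    ConvLayerParams,
    DenseParams,
    PoolSpec,
    TrainedModel,
    _backward_batch,
    _forward_batch,
    _init_params,
    conv1d_forward,
    dense_forward,
    forward,
    global_avg_pool,
    load_model,
    pool1d,
    predict,
    relu,
    save_model,
    train,
)
from cottonfvfm.preprocess import ScalerState


def conv_oracle(x, kernels, bias):
    """Triple-loop valid cross-correlation."""
    C, W = x.shape
    F, _, K = kernels.shape
    out = np.zeros((F, W - K + 1))
    for j in range(F):
        for p in range(W - K + 1):
            acc = bias[j]
            for i in range(C):
                for k in range(K):
                    acc += kernels[j, i, k] * x[i, p + k]
            out[j, p] = acc
    return out


def pool_oracle(x, kind, size, stride):
    C, W = x.shape
    n_out = (W - size) // stride + 1
    out = np.zeros((C, n_out))
    for c in range(C):
        for p in range(n_out):
            win = x[c, p * stride : p * stride + size]
            out[c, p] = win.max() if kind == "max" else win.mean()
    return out


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(-2, 0), (3, 3), (0, 0)])
    def test_scalar_values(self, x, expected):
        assert relu(x) == expected


class TestConv:
    def test_identity_kernel_shifts_input(self):
        x = np.arange(1.0, 9.0)[None, :]
        layer = ConvLayerParams(kernels=np.array([[[0.0, 1.0, 0.0]]]), bias=np.zeros(1))
        np.testing.assert_allclose(conv1d_forward(x, layer)[0], x[0, 1:-1])

    def test_box_kernel_forced_sums(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        layer = ConvLayerParams(kernels=np.array([[[1.0, 1.0, 1.0]]]), bias=np.zeros(1))
        np.testing.assert_allclose(conv1d_forward(x, layer)[0], [6.0, 9.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            C, F, K = rng.integers(1, 4), rng.integers(1, 4), int(rng.integers(1, 4))
            W = int(rng.integers(K, K + 8))
            x = rng.normal(size=(C, W))
            layer = ConvLayerParams(
                kernels=rng.normal(size=(F, C, K)), bias=rng.normal(size=F)
            )
            np.testing.assert_allclose(
                conv1d_forward(x, layer),
                conv_oracle(x, layer.kernels, layer.bias),
                atol=1e-12,
            )

    def test_too_short_input_rejected(self):
        layer = ConvLayerParams(kernels=np.ones((1, 1, 3)), bias=np.zeros(1))
        with pytest.raises(ValueError, match="shorter"):
            conv1d_forward(np.ones((1, 2)), layer)


class TestPooling:
    def test_max_and_average_examples(self):
        x = np.array([[1.0, 3.0, 2.0, 5.0]])
        np.testing.assert_allclose(pool1d(x, PoolSpec("max", 2, 2))[0], [3.0, 5.0])
        np.testing.assert_allclose(pool1d(x, PoolSpec("average", 2, 2))[0], [2.0, 3.5])

    def test_trailing_remainder_dropped(self):
        x = np.array([[1.0, 3.0, 2.0]])
        np.testing.assert_allclose(pool1d(x, PoolSpec("max", 2, 2))[0], [3.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            C = int(rng.integers(1, 4))
            size = int(rng.integers(1, 4))
            stride = int(rng.integers(1, 4))
            W = int(rng.integers(size, size + 9))
            kind = "max" if rng.integers(2) else "average"
            x = rng.normal(size=(C, W))
            np.testing.assert_allclose(
                pool1d(x, PoolSpec(kind, size, stride)),
                pool_oracle(x, kind, size, stride),
                atol=1e-12,
            )


class TestGlobalAveragePool:
    def test_channel_mean(self):
        np.testing.assert_allclose(global_avg_pool(np.array([[2.0, 4.0, 6.0]])), [4.0])

    def test_position_permutation_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 9))
        perm = rng.permutation(9)
        np.testing.assert_allclose(global_avg_pool(x), global_avg_pool(x[:, perm]))

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            x = rng.normal(size=(int(rng.integers(1, 5)), int(rng.integers(1, 10))))
            np.testing.assert_allclose(
                global_avg_pool(x), [row.sum() / row.size for row in x], atol=1e-12
            )


class TestDense:
    def test_examples(self):
        assert dense_forward(np.ones(2), DenseParams(np.array([0.5, 0.5]), 0.0)) == 1.0
        assert dense_forward(np.arange(3.0), DenseParams(np.zeros(3), 2.5)) == 2.5

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            v = rng.normal(size=16)
            w = rng.normal(size=16)
            b = float(rng.normal())
            oracle = sum(wi * vi for wi, vi in zip(w, v)) + b
            assert abs(dense_forward(v, DenseParams(w, b)) - oracle) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dense_forward(np.ones(4), DenseParams(np.ones(3), 0.0))


def tiny_model(config: CNNConfig, seed=0, n_features=20) -> TrainedModel:
    rng = np.random.default_rng(seed)
    conv_layers, dense = _init_params(config, rng)
    scaler = ScalerState(
        x_center=np.zeros(n_features), x_scale=np.ones(n_features),
        y_center=0.0, y_scale=1.0,
    )
    return TrainedModel(config=config, conv_layers=conv_layers, dense=dense,
                        scaler=scaler, history=[])


class TestForward:
    def test_scalar_output_and_length_bookkeeping(self):
        config = CNNConfig(seed=1)
        model = tiny_model(config, n_features=1024)
        x = np.random.default_rng(0).normal(size=1024)
        # trace the shapes through the stack
        h = x[None, :]
        for layer in model.conv_layers:
            h = relu(conv1d_forward(h, layer))
        assert h.shape == (16, 1014)
        h = pool1d(h, config.pool)
        assert h.shape == (16, 507)
        v = global_avg_pool(h)
        assert v.shape == (16,)
        out = forward(model, x)
        assert np.isscalar(out)
        assert out == pytest.approx(dense_forward(v, model.dense))

    def test_zero_input_with_zero_biases_yields_dense_bias(self):
        model = tiny_model(CNNConfig(seed=2), n_features=64)
        model.dense.bias = 0.37
        assert forward(model, np.zeros(64)) == pytest.approx(0.37)

    def test_degenerate_config_matches_hand_composition(self):
        # 1 filter, W=20: the whole network reduces to an explicit chain of
        # the already-oracle-checked operators
        config = CNNConfig(n_filters=1, seed=5)
        model = tiny_model(config, n_features=20)
        x = np.random.default_rng(9).normal(size=20)
        h = x[None, :]
        for layer in model.conv_layers:
            h = np.maximum(0, conv_oracle(h, layer.kernels, layer.bias))
        h = pool_oracle(h, "max", 2, 2)
        v = np.array([row.mean() for row in h])
        expected = float(model.dense.weights @ v + model.dense.bias)
        assert forward(model, x) == pytest.approx(expected, abs=1e-12)

    def test_batched_forward_agrees_with_single_sample(self):
        config = CNNConfig(seed=3)
        model = tiny_model(config, n_features=40)
        X = np.random.default_rng(4).normal(size=(6, 40))
        batched = _forward_batch((model.conv_layers, model.dense), config, X)
        singles = [forward(model, row) for row in X]
        np.testing.assert_allclose(batched, singles, atol=1e-12)

    def test_too_short_input_rejected(self):
        model = tiny_model(CNNConfig(seed=1), n_features=8)
        with pytest.raises(ValueError, match="minimum"):
            forward(model, np.ones(8))


class TestGradients:
    def test_finite_difference_check(self):
        """Hand-derived backprop matches central finite differences."""
        config = CNNConfig(n_conv_layers=2, n_filters=3, seed=8)
        rng = np.random.default_rng(8)
        conv_layers, dense = _init_params(config, rng)
        params = (conv_layers, dense)
        X = rng.normal(size=(4, 15))
        y = rng.normal(size=4)

        def loss_fn():
            pred = _forward_batch(params, config, X)
            return float(np.mean(np.abs(pred - y)))

        pred, cache = _forward_batch(params, config, X, want_cache=True)
        grad_pred = np.sign(pred - y) / y.size
        conv_grads, (gdw, gdb) = _backward_batch(params, config, cache, grad_pred)

        eps = 1e-6
        # spot-check a handful of coordinates in every tensor
        for li, (gk, gb) in enumerate(conv_grads):
            for idx in [(0, 0, 0), (1, 0, 1), (2, -1, -1)]:
                orig = conv_layers[li].kernels[idx]
                conv_layers[li].kernels[idx] = orig + eps
                up = loss_fn()
                conv_layers[li].kernels[idx] = orig - eps
                down = loss_fn()
                conv_layers[li].kernels[idx] = orig
                assert gk[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)
            orig = conv_layers[li].bias[0]
            conv_layers[li].bias[0] = orig + eps
            up = loss_fn()
            conv_layers[li].bias[0] = orig - eps
            down = loss_fn()
            conv_layers[li].bias[0] = orig
            assert gb[0] == pytest.approx((up - down) / (2 * eps), abs=1e-5)
        for i in range(3):
            orig = dense.weights[i]
            dense.weights[i] = orig + eps
            up = loss_fn()
            dense.weights[i] = orig - eps
            down = loss_fn()
            dense.weights[i] = orig
            assert gdw[i] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestTraining:
    def _toy_data(self, n=12, w=30, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.2, 0.6, size=(n, w))
        y = 0.7 + 0.2 * X.mean(axis=1)
        return X, y

    def test_deterministic_given_seed(self):
        X, y = self._toy_data()
        cfg = CNNConfig(epochs=5, seed=7)
        a = train(X, y, cfg)
        b = train(X, y, cfg)
        assert a.history == b.history
        for la, lb in zip(a.conv_layers, b.conv_layers):
            np.testing.assert_array_equal(la.kernels, lb.kernels)
        np.testing.assert_array_equal(a.dense.weights, b.dense.weights)

    def test_zero_learning_rate_freezes_parameters(self):
        X, y = self._toy_data()
        cfg = CNNConfig(epochs=4, learning_rate=0.0, seed=7)
        model = train(X, y, cfg)
        fresh_layers, fresh_dense = _init_params(CNNConfig(epochs=4, seed=7), np.random.default_rng(7))
        for la, lf in zip(model.conv_layers, fresh_layers):
            np.testing.assert_array_equal(la.kernels, lf.kernels)
        assert len(set(np.round(model.history, 15))) == 1  # flat history

    def test_loss_decreases_early(self):
        X, y = self._toy_data(n=20, w=40, seed=1)
        model = train(X, y, CNNConfig(epochs=50, seed=3))
        assert model.history[49] < model.history[0]

    def test_history_length_matches_epochs(self):
        X, y = self._toy_data()
        model = train(X, y, CNNConfig(epochs=7, seed=1))
        assert len(model.history) == 7


class TestPredict:
    def test_channel_count_mismatch_names_sizes(self):
        X, y = np.random.default_rng(0).uniform(0.2, 0.6, (10, 30)), np.linspace(0.7, 0.8, 10)
        model = train(X, y, CNNConfig(epochs=2, seed=1))
        with pytest.raises(ValueError, match="30"):
            predict(model, np.ones((2, 29)))

    def test_predictions_in_plausible_target_range(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.2, 0.6, (15, 30))
        y = 0.75 + 0.05 * rng.normal(size=15)
        model = train(X, y, CNNConfig(epochs=30, seed=2))
        preds = predict(model, X)
        assert np.all(preds > y.mean() - 3 * y.std() - 0.1)
        assert np.all(preds < y.mean() + 3 * y.std() + 0.1)

    def test_save_load_round_trip(self, tmp_path):
        X, y = np.random.default_rng(1).uniform(0.2, 0.6, (10, 25)), np.linspace(0.7, 0.8, 10)
        model = train(X, y, CNNConfig(epochs=3, seed=4))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict(model, X), predict(back, X))
        assert back.config == model.config
        assert back.history == model.history
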