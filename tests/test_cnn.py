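"""CNN building blocks against brute-force oracles, plus training behavior."""

import numpy as np
import pytest

from eegmusic import cnn as C
from eegmusic.recording import EEGRecording


class TestInputTensor:
    def test_shape_and_values(self, small_recording):
        t = C.to_input_tensor(small_recording)
        assert t.shape == (3, 500, 1)
        np.testing.assert_array_equal(t[:, :, 0], small_recording.data)

    def test_roundtrip(self, small_recording):
        t = C.to_input_tensor(small_recording)
        back = C.tensor_to_recording(t, fs=small_recording.fs, channel_labels=small_recording.channel_labels)
        np.testing.assert_array_equal(back.data, small_recording.data)


class TestConvForward:
    def test_identity_kernel(self, rng):
        x = np.abs(rng.normal(size=(1, 4, 10)))
        W = np.ones((1, 1, 1, 1))
        out = C.conv_forward(x, W, np.zeros(1), "relu")
        np.testing.assert_allclose(out, x)

    def test_negative_bias_relu_zeroes(self, rng):
        x = rng.normal(size=(2, 3, 8))
        W = np.zeros((4, 2, 1, 3))
        out = C.conv_forward(x, W, -np.ones(4), "relu")
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_quadruple_loop_oracle(self, rng):
        x = rng.normal(size=(2, 5, 5))
        W = rng.normal(size=(3, 2, 2, 2))
        b = rng.normal(size=3)
        out = C.conv_forward(x, W, b, "linear")
        expected = np.zeros((3, 4, 4))
        for f in range(3):
            for i in range(4):
                for j in range(4):
                    acc = b[f]
                    for c in range(2):
                        for u in range(2):
                            for v in range(2):
                                acc += x[c, i + u, j + v] * W[f, c, u, v]
                    expected[f, i, j] = acc
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_oversized_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            C.conv_forward(rng.normal(size=(1, 2, 2)), np.ones((1, 1, 3, 3)), np.zeros(1))


class TestPoolForward:
    def test_max_pool_2x2(self):
        out = C.pool_forward(np.array([[[1.0, 2.0], [3.0, 4.0]]]), (2, 2), "max")
        assert out[0, 0, 0] == 4.0

    def test_avg_pool_2x2(self):
        out = C.pool_forward(np.array([[[1.0, 2.0], [3.0, 4.0]]]), (2, 2), "avg")
        assert out[0, 0, 0] == 2.5

    def test_affine_contract(self):
        maps = np.full((2, 4, 4), 3.0)
        out = C.pool_forward(maps, (2, 2), "max", beta=2.0, b=1.0)
        np.testing.assert_array_equal(out, 7.0)


class TestSoftmaxAndLoss:
    def test_symmetric_logits(self):
        p = C.softmax_out(np.zeros(3), np.zeros((3, 2)), np.zeros(2))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_extreme_logits_stable(self):
        p = C.softmax_out(np.array([1.0]), np.array([[1000.0, 0.0]]), np.zeros(2))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        logits = rng.normal(size=4) * 3
        p = C.softmax_out(logits, np.eye(4), np.zeros(4))
        direct = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(p, direct, atol=1e-12)

    def test_cross_entropy_perfect_prediction(self):
        preds = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert C.cross_entropy(preds, labels) == pytest.approx(0.0, abs=1e-10)

    def test_cross_entropy_uniform_is_ln2(self):
        preds = np.full((7, 2), 0.5)
        labels = np.eye(2)[np.array([0, 1, 0, 1, 1, 0, 0])]
        assert C.cross_entropy(preds, labels) == pytest.approx(np.log(2))

    def test_cross_entropy_matches_double_loop(self, rng):
        p = rng.dirichlet([1, 1], size=10)
        y = np.eye(2)[rng.integers(0, 2, size=10)]
        loop = -sum(
            y[n, i] * np.log(p[n, i]) for n in range(10) for i in range(2)
        ) / 10
        assert C.cross_entropy(p, y) == pytest.approx(loop, abs=1e-12)


class TestArchitecture:
    def test_default_is_valid_and_has_four_conv_pool_pairs(self):
        specs = C.default_architecture()
        kinds = [s.kind for s in specs]
        assert kinds.count("conv") == 4
        assert kinds.count("pool") == 4
        assert kinds[-1] == "softmax_out"

    @pytest.mark.parametrize(
        "kinds",
        [
            ["conv", "conv", "pool", "softmax_out"],  # conv not followed by pool
            ["pool", "softmax_out"],  # pool without conv
            ["conv", "pool", "fc"],  # missing softmax head
            ["fc", "conv", "pool", "softmax_out"],  # conv after dense
        ],
    )
    def test_invalid_alternation_rejected(self, kinds):
        specs = [C.LayerSpec(k, kernel=(1, 2), n_filters=2) for k in kinds]
        with pytest.raises(ValueError):
            C.validate_architecture(specs)

    def test_layerspec_validation(self):
        with pytest.raises(ValueError):
            C.LayerSpec("conv", kernel=(0, 1))
        with pytest.raises(ValueError):
            C.LayerSpec("fc", dropout_p=1.0)


def _tiny_specs(dropout=0.0, l1=0.0):
    return [
        C.LayerSpec("conv", kernel=(1, 3), n_filters=2, activation="tanh"),
        C.LayerSpec("pool", kernel=(1, 2), pool_mode="max"),
        C.LayerSpec("conv", kernel=(2, 3), n_filters=3, activation="sigmoid"),
        C.LayerSpec("pool", kernel=(1, 2), pool_mode="avg"),
        C.LayerSpec("fc", n_filters=5, activation="relu", dropout_p=dropout, l1_lambda=l1),
        C.LayerSpec("softmax_out", n_filters=2, l1_lambda=l1),
    ]


class TestGradientsAndTraining:
    def test_finite_difference_gradient_check_all_layer_types(self, rng):
        """Analytic reverse-mode gradients vs central differences on a tiny
        2-channel x 16-sample net covering conv/max-pool/avg-pool/fc/softmax."""
        model = C.CNNModel(specs=_tiny_specs(l1=1e-3), input_shape=(2, 16), seed=1)
        X = rng.normal(size=(4, 2, 16))
        y = np.array([0, 1, 0, 1])
        model.loss_and_grads(X, y, train=False)
        grads = [
            (layer, name, gname, getattr(layer, gname).copy())
            for layer in model.layers
            for name, _, gname, _ in layer.params()
        ]
        h = 1e-5
        max_rel = 0.0
        for layer, name, gname, g in grads:
            arr = {n: a for n, a, _, _ in layer.params()}[name]
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                lp = model.loss_and_grads(X, y, train=False)
                arr[idx] = orig - h
                lm = model.loss_and_grads(X, y, train=False)
                arr[idx] = orig
                num = (lp - lm) / (2 * h)
                max_rel = max(max_rel, abs(num - g[idx]) / max(abs(num), abs(g[idx]), 1e-8))
        assert max_rel < 1e-4

    def test_zero_learning_rate_keeps_parameters(self, rng):
        model = C.CNNModel(specs=_tiny_specs(), input_shape=(2, 16), learning_rate=0.0, seed=0)
        X = rng.normal(size=(4, 2, 16))
        y = np.array([0, 1, 1, 0])
        before = [arr.copy() for l in model.layers for _, arr, _, _ in l.params()]
        C.backward_and_update(model, (X, y))
        after = [arr for l in model.layers for _, arr, _, _ in l.params()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)

    def test_loss_decreases_under_small_steps(self, rng):
        model = C.CNNModel(specs=_tiny_specs(), input_shape=(2, 16), learning_rate=0.005, seed=2)
        X = rng.normal(size=(2, 2, 16))
        y = np.array([0, 1])
        losses = [C.backward_and_update(model, (X, y)) for _ in range(30)]
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(losses, losses[1:]))

    def test_train_requires_both_classes(self, rng):
        with pytest.raises(ValueError):
            C.train_cnn(rng.normal(size=(5, 2, 16)), np.zeros(5, dtype=int), specs=_tiny_specs(), epochs=1)

    def test_deterministic_loss_curve(self, rng):
        X = rng.normal(size=(6, 2, 16))
        y = np.array([0, 1] * 3)
        a = C.train_cnn(X, y, specs=_tiny_specs(dropout=0.3), epochs=5, seed=3)
        b = C.train_cnn(X, y, specs=_tiny_specs(dropout=0.3), epochs=5, seed=3)
        assert a.loss_history == b.loss_history

    def test_l1_shrinks_weight_mass(self, rng):
        X = rng.normal(size=(8, 2, 16))
        y = np.array([0, 1] * 4)
        plain = C.train_cnn(X, y, specs=_tiny_specs(l1=0.0), epochs=40, seed=4)
        reg = C.train_cnn(X, y, specs=_tiny_specs(l1=1e-2), epochs=40, seed=4)
        assert reg.sum_abs_weights() < plain.sum_abs_weights()

    def test_serialization_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(4, 2, 16))
        y = np.array([0, 1, 0, 1])
        model = C.train_cnn(X, y, specs=_tiny_specs(), epochs=3, seed=5)
        path = tmp_path / "cnn.json"
        model.save(path)
        loaded = C.CNNModel.load(path)
        np.testing.assert_allclose(
            C.predict_proba(loaded, X), C.predict_proba(model, X), atol=1e-12
        )

    def test_softmax_rows_sum_to_one(self, rng):
        model = C.CNNModel(specs=_tiny_specs(), input_shape=(2, 16), seed=6)
        p = model.forward(rng.normal(size=(9, 2, 16)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
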