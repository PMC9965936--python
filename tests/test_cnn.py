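"""Convolutional classifier: forward pass, gradients, training, refinement."""

import numpy as np
import pytest

from hhocnn.cnn import (
    CNNConfig,
    CNNModel,
    TrainConfig,
    conv_forward,
    predict,
    prepare_images,
    refine_hho,
    train_gd,
)


class TestConvForward:
    def test_zero_kernel_annihilates(self, rng):
        x = rng.normal(size=(5, 5))
        out = conv_forward(x, np.zeros((3, 3)))
        np.testing.assert_array_equal(out, np.zeros((3, 3)))

    def test_identity_kernel(self, rng):
        x = rng.normal(size=(4, 6))
        np.testing.assert_allclose(conv_forward(x, np.ones((1, 1))), x)

    def test_hand_enumerated_sliding_window(self):
        x = np.arange(9, dtype=float).reshape(3, 3)
        k = np.array([[1.0, 2.0], [3.0, 4.0]])
        # each output = sum of elementwise product over the 2x2 window
        expected = np.array(
            [
                [1 * 0 + 2 * 1 + 3 * 3 + 4 * 4, 1 * 1 + 2 * 2 + 3 * 4 + 4 * 5],
                [1 * 3 + 2 * 4 + 3 * 6 + 4 * 7, 1 * 4 + 2 * 5 + 3 * 7 + 4 * 8],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(conv_forward(x, k), expected)

    def test_stride_and_padding(self, rng):
        x = rng.normal(size=(5, 5))
        out = conv_forward(x, np.ones((1, 1)), stride=2)
        np.testing.assert_allclose(out, x[::2, ::2])
        out = conv_forward(x, np.ones((3, 3)), padding=1)
        assert out.shape == (5, 5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            conv_forward(np.zeros((2, 4, 4)), np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            conv_forward(np.zeros((2, 2)), np.zeros((3, 3)))


def tiny_model(seed=0):
    return CNNModel(CNNConfig(input_side=6, n_filters=2, kernel=3, pool=2, seed=seed))


class TestForward:
    def test_zero_weights_give_half(self):
        model = tiny_model()
        model.set_all_vector(np.zeros(model.get_all_vector().shape))
        x = np.random.default_rng(0).uniform(size=(3, 6, 6))
        np.testing.assert_allclose(model.forward(x), 0.5)

    def test_relu_kills_negative_preactivations(self):
        model = tiny_model()
        model.set_all_vector(np.zeros(model.get_all_vector().shape))
        model.conv_b[:] = -5.0  # all pre-activations negative
        model.fc_w[:] = 1.0
        x = np.random.default_rng(1).uniform(size=(2, 6, 6))
        # pooled ReLU output is zero everywhere, so the logit is fc_b = 0
        np.testing.assert_allclose(model.forward(x), 0.5)

    def test_manual_layerwise_oracle(self):
        # 4x4 input, one 2x2 filter, 2x2 pool, 1-unit FC: hand computation
        model = CNNModel(CNNConfig(input_side=4, n_filters=1, kernel=2, pool=2))
        model.conv_w = np.array([[[1.0, -1.0], [0.5, 2.0]]])
        model.conv_b = np.array([0.1])
        # pooled grid is 1x1 (3x3 conv plane, one 2x2 pool window): fc dim 1
        assert model.config.fc_dim == 1
        model.fc_w = np.array([0.2])
        model.fc_b = -0.05
        x = np.array(
            [
                [0.0, 0.1, 0.2, 0.3],
                [0.4, 0.5, 0.6, 0.7],
                [0.8, 0.9, 1.0, 0.1],
                [0.2, 0.3, 0.4, 0.5],
            ]
        )
        s = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                w = x[i : i + 2, j : j + 2]
                s[i, j] = (
                    1.0 * w[0, 0] - 1.0 * w[0, 1] + 0.5 * w[1, 0] + 2.0 * w[1, 1] + 0.1
                )
        t = np.maximum(s, 0)
        pooled = t[0:2, 0:2].max()  # 3x3 plane -> one 2x2 pool window
        z = 0.2 * pooled - 0.05
        expected = 1.0 / (1.0 + np.exp(-z))
        got = model.forward(x[None])[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_wrong_input_size_rejected(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 5, 5)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        model = tiny_model(seed=3)
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(4, 6, 6))
        y = np.array([0.0, 1.0, 1.0, 0.0])
        _, grads = model.gradients(X, y)
        eps = 1e-6
        vec = model.get_all_vector()
        flat_grads = np.concatenate(
            [
                grads["conv_w"].ravel(),
                grads["conv_b"],
                grads["fc_w"],
                [grads["fc_b"]],
            ]
        )
        rel_errs = []
        idx = rng.choice(vec.size, size=min(40, vec.size), replace=False)
        for i in idx:
            vp, vm = vec.copy(), vec.copy()
            vp[i] += eps
            vm[i] -= eps
            model.set_all_vector(vp)
            lp = model.loss(X, y)
            model.set_all_vector(vm)
            lm = model.loss(X, y)
            fd = (lp - lm) / (2 * eps)
            denom = max(abs(fd), abs(flat_grads[i]), 1e-8)
            rel_errs.append(abs(fd - flat_grads[i]) / denom)
        assert max(rel_errs) < 1e-4


class TestTraining:
    def make_toy(self, n=16, side=6, seed=0):
        rng = np.random.default_rng(seed)
        y = np.tile([0.0, 1.0], n // 2)
        X = rng.uniform(0, 0.2, size=(n, side, side))
        X[y == 1] += 0.6  # bright images are positive
        return X, y

    def test_zero_learning_rate_no_update(self):
        model = tiny_model()
        before = model.get_all_vector().copy()
        X, y = self.make_toy()
        train_gd(model, X, y, TrainConfig(learning_rate=0.0, epochs=3))
        np.testing.assert_array_equal(model.get_all_vector(), before)

    def test_loss_decreases_on_separable_toy(self):
        model = tiny_model(seed=1)
        X, y = self.make_toy()
        hist = train_gd(
            model, X, y, TrainConfig(learning_rate=0.05, epochs=20, batch_size=16)
        )
        assert hist[-1] < hist[0]
        # full-batch descent at a small step decreases nearly monotonically
        assert sum(b > a + 1e-9 for a, b in zip(hist, hist[1:])) <= 2

    def test_single_class_rejected(self):
        model = tiny_model()
        X = np.zeros((4, 6, 6))
        with pytest.raises(ValueError):
            train_gd(model, X, np.ones(4))

    def test_deterministic_given_seed(self):
        X, y = self.make_toy()
        runs = []
        for _ in range(2):
            model = tiny_model(seed=2)
            train_gd(model, X, y, TrainConfig(epochs=5, seed=11))
            runs.append(model.get_all_vector())
        np.testing.assert_array_equal(runs[0], runs[1])


class TestRefinement:
    def test_never_increases_training_loss(self):
        X = np.random.default_rng(5).uniform(size=(10, 6, 6))
        y = np.tile([0.0, 1.0], 5)
        model = tiny_model(seed=4)
        train_gd(model, X, y, TrainConfig(epochs=10))
        before = model.loss(X, y)
        refined, info = refine_hho(model, X, y, TrainConfig(), seed=3)
        assert refined.loss(X, y) <= before + 1e-12

    def test_improves_from_random_init(self):
        X = np.random.default_rng(6).uniform(size=(12, 6, 6))
        y = np.tile([0.0, 1.0], 6)
        model = tiny_model(seed=8)
        init_loss = model.loss(X, y)
        cfg = TrainConfig(refine_population=20, refine_iterations=50)
        refined, info = refine_hho(model, X, y, cfg, seed=1)
        assert refined.loss(X, y) < init_loss

    def test_zero_budget_returns_unchanged(self):
        X = np.random.default_rng(7).uniform(size=(4, 6, 6))
        y = np.array([0.0, 1.0, 0.0, 1.0])
        model = tiny_model()
        refined, info = refine_hho(
            model, X, y, TrainConfig(refine_iterations=0), seed=0
        )
        np.testing.assert_array_equal(
            refined.get_all_vector(), model.get_all_vector()
        )
        assert not info["accepted"]

    def test_same_seed_identical_weights(self):
        X = np.random.default_rng(8).uniform(size=(6, 6, 6))
        y = np.tile([0.0, 1.0], 3)
        model = tiny_model(seed=9)
        a, _ = refine_hho(model, X, y, TrainConfig(), seed=21)
        b, _ = refine_hho(model, X, y, TrainConfig(), seed=21)
        np.testing.assert_array_equal(a.get_all_vector(), b.get_all_vector())


class TestPredictAndSerialization:
    def test_empty_split(self):
        model = tiny_model()
        labels, probs = predict(model, np.zeros((0, 6, 6)))
        assert len(labels) == 0 and len(probs) == 0

    def test_half_probability_maps_to_one(self):
        model = tiny_model()
        model.set_all_vector(np.zeros(model.get_all_vector().shape))
        labels, probs = predict(model, np.random.default_rng(0).uniform(size=(2, 6, 6)))
        assert (probs == 0.5).all()
        assert (labels == 1).all()

    def test_save_load_roundtrip_exact(self, tmp_path):
        model = tiny_model(seed=12)
        path = tmp_path / "model.json"
        model.save(path)
        back = CNNModel.load(path)
        assert back.config == model.config
        np.testing.assert_array_equal(back.get_all_vector(), model.get_all_vector())

    def test_prepare_images_scaling_and_resize(self):
        img = np.full((8, 8), 255, dtype=np.uint8)
        X = prepare_images([img], side=8)
        np.testing.assert_allclose(X[0], 1.0)
        Xr = prepare_images([img], side=4)
        assert Xr.shape == (1, 4, 4)
        np.testing.assert_allclose(Xr[0], 1.0, atol=1e-9)
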