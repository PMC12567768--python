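"""3D convolutional autoencoder: gradients, shapes, training, features."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

import eegdaae as E
from eegdaae._nn import Activation, Adam, Conv3D, ConvTranspose3D
from eegdaae.daae import DaaeConfig, build_daae, reconstruction_mse, train_daae


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestGradients:
    """Analytic backward passes agree with central finite differences."""

    @pytest.mark.parametrize("layer_cls", [Conv3D, ConvTranspose3D])
    @pytest.mark.parametrize("kernel", [(3, 3, 3), (5, 5, 3)])
    def test_layer_gradients(self, layer_cls, kernel):
        rng = np.random.default_rng(0)
        layer = layer_cls(2, 3, kernel, stride=2, initializer="glorot_uniform", rng=rng)
        x = rng.standard_normal((2, 4, 4, 4, 2))
        proj = rng.standard_normal(layer.forward(x).shape)  # random scalar projection

        def loss():
            return float((layer.forward(x) * proj).sum())

        loss()
        dx = layer.backward(proj)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-7)
        np.testing.assert_allclose(layer.dW, numeric_grad(loss, layer.W), atol=1e-6)
        np.testing.assert_allclose(layer.db, numeric_grad(loss, layer.b), atol=1e-6)

    @pytest.mark.parametrize("name", ["relu", "elu", "sigmoid", "selu"])
    def test_activation_gradients(self, name):
        rng = np.random.default_rng(1)
        act = Activation(name)
        x = rng.standard_normal((3, 5)) + 0.05  # keep away from relu kink
        proj = rng.standard_normal((3, 5))

        def loss():
            return float((act.forward(x) * proj).sum())

        loss()
        dx = act.backward(proj)
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=1e-6)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(n_layers=4, n_units=(16, 16, 16, 16)),
        dict(n_units=(20,)),
        dict(kernel=(7, 7, 7)),
        dict(activation="tanh"),
        dict(optimizer="sgd"),
        dict(initializer="zeros"),
        dict(epochs=0),
        dict(n_layers=2, n_units=(16,)),
    ])
    def test_out_of_domain_values_rejected(self, bad):
        with pytest.raises(ValueError):
            DaaeConfig(**bad)

    def test_search_space_defaults_valid(self):
        DaaeConfig(n_layers=3, n_units=(64, 48, 32), kernel=(5, 5, 3),
                   activation="selu", optimizer="adamw", initializer="he_normal")


class TestModelShapes:
    def test_autoencoder_closure(self):
        model = build_daae(DaaeConfig(seed=0))
        x = np.random.default_rng(0).standard_normal((2, 32, 32, 32, 1))
        assert model.forward(x).shape == (2, 32, 32, 32, 1)

    def test_two_layer_latent_is_8_cubed(self):
        cfg = DaaeConfig(n_layers=2, n_units=(48, 32), seed=0)
        model = build_daae(cfg)
        assert model.latent_shape() == (8, 8, 8, 32)
        x = np.random.default_rng(0).standard_normal((1, 32, 32, 32, 1))
        assert model.encode(x).shape == (1, 8, 8, 8, 32)
        assert model.forward(x).shape == (1, 32, 32, 32, 1)

    def test_identical_seed_identical_initial_parameters(self):
        cfg = DaaeConfig(seed=5)
        a, b = build_daae(cfg), build_daae(cfg)
        for la, lb in zip(a.layers, b.layers):
            for pa, pb in zip(la.params, lb.params):
                np.testing.assert_array_equal(pa, pb)


def smooth_cubes(n: int, seed: int) -> np.ndarray:
    """Spatially smooth cubes: rasterized random electrode patterns modulated
    by a random temporal envelope (structure a small autoencoder can learn)."""
    layout = E.project_montage()
    rng = np.random.default_rng(seed)
    cubes = []
    for _ in range(n):
        frame = E.rasterize(rng.standard_normal(24), layout).grid
        envelope = np.sin(np.linspace(0, 2 * np.pi, 32) + rng.uniform(0, 2 * np.pi))
        cubes.append(envelope[:, None, None] * frame[None])
    return np.stack(cubes)


class TestTraining:
    def test_identity_task_halves_loss_and_trends_down(self):
        x = smooth_cubes(10, seed=2)
        cfg = DaaeConfig(epochs=6, batch_size=2, learning_rate=3e-3, seed=0)
        trained = train_daae(build_daae(cfg), x, x, cfg)
        final = reconstruction_mse(trained, x, x)
        assert final < 0.5 * trained.initial_loss
        hist = trained.loss_history
        assert len(hist) == cfg.epochs
        assert np.mean(hist[-3:]) <= np.mean(hist[:3])

    def test_zero_data_zero_loss(self):
        x = np.zeros((4, 32, 32, 32))
        cfg = DaaeConfig(epochs=3, batch_size=2, seed=0)
        trained = train_daae(build_daae(cfg), x, x, cfg)
        assert trained.initial_loss == 0.0
        assert trained.loss_history == [0.0, 0.0, 0.0]

    def test_training_deterministic_at_fixed_seed(self):
        x = smooth_cubes(6, seed=3)
        cfg = DaaeConfig(epochs=2, batch_size=2, seed=9)
        a = train_daae(build_daae(cfg), x, x, cfg)
        b = train_daae(build_daae(cfg), x, x, cfg)
        assert a.loss_history == b.loss_history
        np.testing.assert_array_equal(E.encode(a, x), E.encode(b, x))

    def test_shape_mismatch_rejected(self):
        cfg = DaaeConfig(epochs=1, seed=0)
        with pytest.raises(ValueError):
            train_daae(build_daae(cfg), np.zeros((2, 32, 32, 32)),
                       np.zeros((3, 32, 32, 32)), cfg)


class TestFeatures:
    def test_encode_deterministic_and_finite(self):
        x = smooth_cubes(3, seed=4)
        cfg = DaaeConfig(epochs=1, batch_size=2, seed=0)
        trained = train_daae(build_daae(cfg), x, x, cfg)
        z1, z2 = E.encode(trained, x[0]), E.encode(trained, x[0])
        np.testing.assert_array_equal(z1, z2)
        assert np.isfinite(z1).all()
        assert z1.shape == trained.model.latent_shape()

    def test_aggregate_is_channel_mean(self):
        ones = np.ones((4, 4, 4, 16))
        np.testing.assert_array_equal(E.aggregate_features(ones), np.ones(16))
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 4, 4, 3))
        perm = rng.permutation(64)
        z_perm = z.reshape(64, 3)[perm].reshape(4, 4, 4, 3)
        np.testing.assert_allclose(E.aggregate_features(z),
                                   E.aggregate_features(z_perm), atol=1e-12)
        single = rng.standard_normal((2, 2, 2, 1))
        np.testing.assert_allclose(E.aggregate_features(single),
                                   [single.mean()])


class TestEstimator:
    def test_sklearn_params_roundtrip_and_clone(self):
        est = E.ConvAutoencoder3D(epochs=2, n_units=(32,), random_state=7)
        params = est.get_params()
        assert params["n_units"] == (32,)
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_transform_requires_fit(self):
        with pytest.raises(NotFittedError):
            E.ConvAutoencoder3D().transform(np.zeros((1, 32, 32, 32)))

    def test_fit_transform_feature_shape(self):
        x = smooth_cubes(6, seed=5)
        est = E.ConvAutoencoder3D(epochs=2, batch_size=2, random_state=0).fit(x)
        feats = est.transform(x)
        assert feats.shape == (6, 16)
        assert est.n_features_out_ == 16
        assert len(est.loss_history_) == 2

    def test_checkpoint_roundtrip(self, tmp_path):
        x = smooth_cubes(4, seed=6)
        est = E.ConvAutoencoder3D(epochs=2, batch_size=2, random_state=1).fit(x)
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = E.ConvAutoencoder3D.load(path)
        np.testing.assert_array_equal(est.transform(x), loaded.transform(x))
        assert loaded.loss_history_ == est.loss_history_


class TestOptimizer:
    def test_adamw_decays_kernels_not_biases(self):
        rng = np.random.default_rng(0)
        layer = Conv3D(1, 1, (3, 3, 3), stride=2, initializer="he_normal", rng=rng)
        x = rng.standard_normal((1, 4, 4, 4, 1))
        opt = Adam([layer], learning_rate=1e-2, kind="adamw", weight_decay=0.5)
        layer.forward(x)
        layer.backward(np.zeros((1, 2, 2, 2, 1)))  # zero gradient: pure decay
        w_before = layer.W.copy()
        b_before = layer.b.copy()
        opt.step()
        assert np.abs(layer.W).sum() < np.abs(w_before).sum()
        np.testing.assert_array_equal(layer.b, b_before)
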