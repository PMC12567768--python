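"""Domain-adaptive 3D convolutional autoencoder (DAAE).

The encoder maps a 32 x 32 x 32 data cube X through ``n_layers`` strided
(stride-2) 3D convolution blocks to a latent tensor Z; the decoder mirrors
the encoder with transposed convolutions back to 32 x 32 x 32 and is
trained to reconstruct a *target-domain* cube X_A (a uniform- or
softmin-weighted combination of trials, see :mod:`eegdaae.domaingen`)
rather than the source cube itself. Training minimizes mean squared error
over voxels; no regularization terms. Latent features for classification
are the per-channel means of Z over its spatial/temporal axes.

Architecture hyperparameters are drawn from a fixed search space:
layers 1-3, units {16, 32, 48, 64}, kernels 3x3x3 or 5x5x3 (time, row,
col), activations {relu, elu, sigmoid, selu}, Glorot/He initializers,
Adam or AdamW. Downsampling uses strided convolution rather than pooling
so the decoder mirror is exact. Batch size 16 and learning rate 1e-3 are
defaults, exposed in the config.

Everything is seeded and deterministic: identical config, data, and seed
give identical loss histories and latent features.

:class:`ConvAutoencoder3D` wraps the model as a scikit-learn style
transformer (``fit(X, y)`` / ``transform``): ``X`` are source cubes,
``y`` the paired target cubes (omit ``y`` for a self-referential
autoencoder baseline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import (ACTIVATIONS, INITIALIZERS, OPTIMIZERS, Activation, Adam,
                  Conv3D, ConvTranspose3D)

__all__ = [
    "KERNEL_CHOICES",
    "UNIT_CHOICES",
    "DaaeConfig",
    "TrainedDaae",
    "build_daae",
    "train_daae",
    "reconstruction_mse",
    "encode",
    "aggregate_features",
    "ConvAutoencoder3D",
]

CUBE_SHAPE = (32, 32, 32)
KERNEL_CHOICES = ((3, 3, 3), (5, 5, 3))
UNIT_CHOICES = (16, 32, 48, 64)
LAYER_CHOICES = (1, 2, 3)


@dataclass(frozen=True)
class DaaeConfig:
    """Hyperparameters of one autoencoder, restricted to the search-space domains."""

    n_layers: int = 1
    n_units: tuple[int, ...] = (16,)
    kernel: tuple[int, int, int] = (3, 3, 3)
    activation: str = "relu"
    optimizer: str = "adam"
    initializer: str = "glorot_uniform"
    epochs: int = 10
    seed: int = 0
    batch_size: int = 16
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_layers not in LAYER_CHOICES:
            raise ValueError(f"n_layers must be in {LAYER_CHOICES}, got {self.n_layers}")
        if len(self.n_units) != self.n_layers:
            raise ValueError(
                f"n_units must list one width per layer ({self.n_layers}), got {self.n_units}"
            )
        for u in self.n_units:
            if u not in UNIT_CHOICES:
                raise ValueError(f"unit width {u} not in {UNIT_CHOICES}")
        if tuple(self.kernel) not in KERNEL_CHOICES:
            raise ValueError(f"kernel {self.kernel} not in {KERNEL_CHOICES}")
        if self.activation not in ACTIVATIONS[:-1]:  # 'linear' is internal only
            raise ValueError(f"activation {self.activation!r} not in {ACTIVATIONS[:-1]}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer {self.optimizer!r} not in {OPTIMIZERS}")
        if self.initializer not in INITIALIZERS:
            raise ValueError(f"initializer {self.initializer!r} not in {INITIALIZERS}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class Autoencoder3D:
    """Encoder/decoder layer stacks over channels-last cubes."""

    def __init__(self, cfg: DaaeConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc: list = []
        c_in = 1
        for units in cfg.n_units:
            enc.append(Conv3D(c_in, units, cfg.kernel, stride=2,
                              initializer=cfg.initializer, rng=rng))
            enc.append(Activation(cfg.activation))
            c_in = units
        dec: list = []
        widths = list(cfg.n_units[:-1][::-1]) + [1]
        for i, units in enumerate(widths):
            dec.append(ConvTranspose3D(c_in, units, cfg.kernel, stride=2,
                                       initializer=cfg.initializer, rng=rng))
            dec.append(Activation(cfg.activation if i < len(widths) - 1 else "linear"))
            c_in = units
        self.encoder_layers = enc
        self.decoder_layers = dec

    @property
    def layers(self):
        return self.encoder_layers + self.decoder_layers

    def encode(self, x: np.ndarray) -> np.ndarray:
        for layer in self.encoder_layers:
            x = layer.forward(x)
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def latent_shape(self) -> tuple[int, int, int, int]:
        d = CUBE_SHAPE[0] >> self.cfg.n_layers  # stride-2 halving per layer
        return (d, d, d, self.cfg.n_units[-1])


@dataclass
class TrainedDaae:
    """Fitted autoencoder plus its training record."""

    model: Autoencoder3D
    config: DaaeConfig
    loss_history: list[float] = field(default_factory=list)
    initial_loss: float = float("nan")


def build_daae(cfg: DaaeConfig) -> Autoencoder3D:
    """Instantiate an untrained autoencoder (parameters seeded from cfg.seed)."""
    return Autoencoder3D(cfg)


def _as_batch(cubes: np.ndarray) -> np.ndarray:
    arr = np.asarray(cubes, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[1:4] != CUBE_SHAPE:
        raise ValueError(f"cubes must have spatial shape {CUBE_SHAPE}, got {arr.shape}")
    if arr.ndim == 4:
        arr = arr[..., None]
    return arr


def _mse(model: Autoencoder3D, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        out = model.forward(x[i:i + batch])
        total += float(((out - y[i:i + batch]) ** 2).sum())
        n += out.size
    return total / max(n, 1)


def train_daae(model: Autoencoder3D, sources: np.ndarray, targets: np.ndarray,
               cfg: DaaeConfig | None = None) -> TrainedDaae:
    """Train on paired (source, target) cubes by minibatch MSE descent.

    ``sources``/``targets``: arrays of shape (n, 32, 32, 32); each source
    cube is paired index-wise with its target cube (the caller applies the
    pairing rule: uniform scheme repeats the shared target per trial,
    softmin pairs trial i with its own target).
    """
    cfg = cfg or model.cfg
    x = _as_batch(sources)
    y = _as_batch(targets)
    if x.shape != y.shape:
        raise ValueError(f"source shape {x.shape} != target shape {y.shape}")
    n = x.shape[0]
    opt = Adam(model.layers, learning_rate=cfg.learning_rate, kind=cfg.optimizer)
    rng = np.random.default_rng(cfg.seed + 1)
    initial = _mse(model, x, y, cfg.batch_size)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            out = model.forward(xb)
            err = out - yb
            epoch_loss += float((err ** 2).sum())
            seen += out.size
            model.backward(2.0 * err / out.size)
            opt.step()
        history.append(epoch_loss / max(seen, 1))
    return TrainedDaae(model=model, config=cfg, loss_history=history, initial_loss=initial)


def reconstruction_mse(trained: TrainedDaae | Autoencoder3D, sources: np.ndarray,
                       targets: np.ndarray, batch_size: int = 16) -> float:
    """Mean squared reconstruction error of sources against targets."""
    model = trained.model if isinstance(trained, TrainedDaae) else trained
    return _mse(model, _as_batch(sources), _as_batch(targets), batch_size)


def encode(trained: TrainedDaae | Autoencoder3D, cubes: np.ndarray) -> np.ndarray:
    """Latent tensor(s) for one cube or a batch of cubes."""
    model = trained.model if isinstance(trained, TrainedDaae) else trained
    single = np.asarray(cubes).ndim == 3
    z = model.encode(_as_batch(cubes))
    return z[0] if single else z


def aggregate_features(latent: np.ndarray) -> np.ndarray:
    """Per-channel spatial means of a latent tensor: (d,d,d,C) -> (C,)."""
    latent = np.asarray(latent)
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent tensor contains non-finite values")
    if latent.ndim == 4:
        return latent.mean(axis=(0, 1, 2))
    if latent.ndim == 5:
        return latent.mean(axis=(1, 2, 3))
    raise ValueError(f"latent must be 4-D or 5-D, got ndim={latent.ndim}")


class ConvAutoencoder3D(TransformerMixin, BaseEstimator):
    """Scikit-learn style 3D convolutional autoencoder transformer.

    ``fit(X, y)`` trains the autoencoder to reconstruct target cubes ``y``
    from source cubes ``X`` (shape ``(n, 32, 32, 32)``); with ``y=None``
    it reduces to a self-referential autoencoder. ``transform(X)`` returns
    the aggregated latent feature vectors, shape ``(n, n_units[-1])``.

    Parameters mirror :class:`DaaeConfig`; ``random_state`` seeds the
    parameter initialization and batch shuffling.
    """

    def __init__(self, n_layers: int = 1, n_units=(16,), kernel=(3, 3, 3),
                 activation: str = "relu", optimizer: str = "adam",
                 initializer: str = "glorot_uniform", epochs: int = 10,
                 batch_size: int = 16, learning_rate: float = 1e-3,
                 random_state: int = 0):
        self.n_layers = n_layers
        self.n_units = n_units
        self.kernel = kernel
        self.activation = activation
        self.optimizer = optimizer
        self.initializer = initializer
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _config(self) -> DaaeConfig:
        return DaaeConfig(
            n_layers=self.n_layers, n_units=tuple(self.n_units),
            kernel=tuple(self.kernel), activation=self.activation,
            optimizer=self.optimizer, initializer=self.initializer,
            epochs=self.epochs, seed=self.random_state,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
        )

    def fit(self, X, y=None):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = X if y is None else np.asarray(y, dtype=float)
        model = build_daae(cfg)
        trained = train_daae(model, X, y, cfg)
        self.model_ = trained
        self.loss_history_ = trained.loss_history
        self.initial_loss_ = trained.initial_loss
        self.n_features_out_ = cfg.n_units[-1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return aggregate_features(encode(self.model_, np.asarray(X, dtype=float)))

    def save(self, path: str | Path) -> None:
        """Checkpoint parameters + config (numpy archive with embedded JSON)."""
        check_is_fitted(self, "model_")
        model = self.model_.model
        arrays = {}
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.params):
                arrays[f"p_{i}_{j}"] = p
        np.savez(
            path, __config__=json.dumps(asdict(self.model_.config)),
            __loss__=np.asarray(self.loss_history_),
            __initial__=self.initial_loss_, **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvAutoencoder3D":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            cfg_dict["n_units"] = tuple(cfg_dict["n_units"])
            cfg_dict["kernel"] = tuple(cfg_dict["kernel"])
            cfg = DaaeConfig(**cfg_dict)
            est = cls(
                n_layers=cfg.n_layers, n_units=cfg.n_units, kernel=cfg.kernel,
                activation=cfg.activation, optimizer=cfg.optimizer,
                initializer=cfg.initializer, epochs=cfg.epochs,
                batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
                random_state=cfg.seed,
            )
            model = build_daae(cfg)
            for i, layer in enumerate(model.layers):
                for j, p in enumerate(layer.params):
                    p[...] = data[f"p_{i}_{j}"]
            est.model_ = TrainedDaae(
                model=model, config=cfg,
                loss_history=list(data["__loss__"]),
                initial_loss=float(data["__initial__"]),
            )
            est.loss_history_ = est.model_.loss_history
            est.initial_loss_ = est.model_.initial_loss
            est.n_features_out_ = cfg.n_units[-1]
        return est
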