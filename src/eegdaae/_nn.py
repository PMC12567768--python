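"""Minimal numpy neural-network primitives for the 3D convolutional autoencoder.

Implements exactly what the autoencoder needs: strided 3D convolution and
its mirrored transposed convolution (both with 'same'-style padding so a
stride-2 conv halves each spatial axis and its transpose restores it),
the relu/elu/sigmoid/selu activations, Glorot/He initializers, and
Adam/AdamW. Layers cache their forward inputs and expose ``backward`` for
plain reverse-mode differentiation; everything is float64 numpy, seeded
and deterministic.

Array layout is channels-last: ``(batch, depth, height, width, channels)``
with depth = time for EEG data cubes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "INITIALIZERS",
    "OPTIMIZERS",
    "make_activation",
    "init_kernel",
    "Conv3D",
    "ConvTranspose3D",
    "Activation",
    "Adam",
]

ACTIVATIONS = ("relu", "elu", "sigmoid", "selu", "linear")
INITIALIZERS = ("glorot_uniform", "glorot_normal", "he_uniform", "he_normal")
OPTIMIZERS = ("adam", "adamw")

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def init_kernel(shape: tuple[int, ...], scheme: str, rng: np.random.Generator) -> np.ndarray:
    """Kernel init; ``shape`` = (kd, kh, kw, c_in, c_out)."""
    if scheme not in INITIALIZERS:
        raise ValueError(f"unknown initializer {scheme!r}; expected one of {INITIALIZERS}")
    receptive = int(np.prod(shape[:-2]))
    fan_in = receptive * shape[-2]
    fan_out = receptive * shape[-1]
    if scheme == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)
    if scheme == "glorot_normal":
        return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)
    if scheme == "he_uniform":
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape)
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Activation:
    """Elementwise activation layer with cached forward pass."""

    def __init__(self, name: str):
        if name not in ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")
        self.name = name
        self._x: np.ndarray | None = None
        self._out: np.ndarray | None = None

    params: tuple = ()
    grads: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n = self.name
        if n == "linear":
            out = x
        elif n == "relu":
            out = np.maximum(x, 0.0)
        elif n == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-x))
        elif n == "elu":
            out = np.where(x > 0, x, np.expm1(x))
        else:  # selu
            out = _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        n = self.name
        if n == "linear":
            return dout
        if n == "relu":
            return dout * (x > 0)
        if n == "sigmoid":
            return dout * out * (1.0 - out)
        if n == "elu":
            return dout * np.where(x > 0, 1.0, np.exp(x))
        return dout * _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


def make_activation(name: str) -> Activation:
    return Activation(name)


def _same_pads(in_size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' strided convolution."""
    out = -(-in_size // stride)  # ceil
    pad_total = max((out - 1) * stride + kernel - in_size, 0)
    before = pad_total // 2
    return out, before, pad_total - before


class Conv3D:
    """Strided 3D convolution, 'same' padding, channels-last."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 stride: int, initializer: str, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.kernel = tuple(kernel)
        self.stride = stride
        self.W = init_kernel((*self.kernel, c_in, c_out), initializer, rng)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._pads: tuple | None = None

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(_same_pads(s, k, self.stride)[0] for s, k in zip(spatial, self.kernel))

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        pads = [_same_pads(x.shape[1 + i], self.kernel[i], s) for i in range(3)]
        self._pads = pads
        xp = np.pad(x, [(0, 0)] + [(p[1], p[2]) for p in pads] + [(0, 0)])
        self._xp = xp
        od, oh, ow = (p[0] for p in pads)
        out = np.broadcast_to(self.b, (x.shape[0], od, oh, ow, self.c_out)).copy()
        kd, kh, kw = self.kernel
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    patch = xp[:, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s, :]
                    out += patch @ self.W[a, b, c]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.stride
        xp, pads = self._xp, self._pads
        od, oh, ow = (p[0] for p in pads)
        kd, kh, kw = self.kernel
        self.dW = np.zeros_like(self.W)
        self.db = dout.sum(axis=(0, 1, 2, 3))
        dxp = np.zeros_like(xp)
        flat_dout = dout.reshape(-1, self.c_out)
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    sl = np.s_[:, a:a + s * od:s, b:b + s * oh:s, c:c + s * ow:s, :]
                    patch = xp[sl]
                    self.dW[a, b, c] = patch.reshape(-1, self.c_in).T @ flat_dout
                    dxp[sl] += dout @ self.W[a, b, c].T
        crop = tuple(
            slice(p[1], dxp.shape[1 + i] - p[2]) for i, p in enumerate(pads)
        )
        return dxp[(slice(None), *crop, slice(None))]


class ConvTranspose3D:
    """Stride-s transposed 3D convolution; exact adjoint of the mirror Conv3D,
    so each spatial axis is multiplied by the stride."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 stride: int, initializer: str, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.kernel = tuple(kernel)
        self.stride = stride
        self.W = init_kernel((*self.kernel, c_in, c_out), initializer, rng)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._pads: tuple | None = None

    @property
    def params(self):
        return (self.W, self.b)

    @property
    def grads(self):
        return (self.dW, self.db)

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        n = x.shape[0]
        ids = x.shape[1:4]
        outs = tuple(i * s for i in ids)
        # pads of the mirror convolution (out -> in), removed after scatter
        pads = [_same_pads(outs[i], self.kernel[i], s) for i in range(3)]
        self._pads = pads
        self._x = x
        kd, kh, kw = self.kernel
        full = tuple(outs[i] + pads[i][1] + pads[i][2] for i in range(3))
        out_pad = np.zeros((n, *full, self.c_out))
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    out_pad[:, a:a + s * ids[0]:s, b:b + s * ids[1]:s,
                            c:c + s * ids[2]:s, :] += x @ self.W[a, b, c]
        crop = tuple(slice(pads[i][1], pads[i][1] + outs[i]) for i in range(3))
        return out_pad[(slice(None), *crop, slice(None))] + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.stride
        x, pads = self._x, self._pads
        ids = x.shape[1:4]
        kd, kh, kw = self.kernel
        dout_pad = np.pad(dout, [(0, 0)] + [(p[1], p[2]) for p in pads] + [(0, 0)])
        self.dW = np.zeros_like(self.W)
        self.db = dout.sum(axis=(0, 1, 2, 3))
        dx = np.zeros_like(x)
        flat_x = x.reshape(-1, self.c_in)
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    patch = dout_pad[:, a:a + s * ids[0]:s, b:b + s * ids[1]:s,
                                     c:c + s * ids[2]:s, :]
                    self.dW[a, b, c] = flat_x.T @ patch.reshape(-1, self.c_out)
                    dx += patch @ self.W[a, b, c].T
        return dx


class Adam:
    """Adam / AdamW (decoupled weight decay) over a flat list of layers."""

    def __init__(self, layers, learning_rate: float = 1e-3, kind: str = "adam",
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        if kind not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {kind!r}; expected one of {OPTIMIZERS}")
        self.layers = [l for l in layers if l.params]
        self.lr, self.kind = learning_rate, kind
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay if kind == "adamw" else 0.0
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                if self.weight_decay and p.ndim > 1:  # decay kernels, not biases
                    update = update + self.weight_decay * p
                p -= self.lr * update
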