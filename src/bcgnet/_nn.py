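"""Minimal numpy neural-network engine for the fixed 2D-CNN topology.

Implements exactly the layer kinds the classifier needs — strided 2D
convolution with "same" padding, max pooling, batch normalization,
inverted dropout, flatten and dense — each with a hand-derived backward
pass, plus Adam and binary cross-entropy with L1 kernel regularization.
This is a static per-layer backprop stack, not a general autodiff system.

Conventions: activations are NHWC float64; convolution padding follows the
TensorFlow "same" rule (output size ceil(n/stride), asymmetric padding with
the extra row/column at the bottom/right); weight init is Glorot uniform
from a seeded generator, so two builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

EPS_BN = 1e-3
BN_MOMENTUM = 0.99


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: no parameters, identity gradients."""

    name = "layer"

    def init_params(self, rng: np.random.Generator, input_shape):
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> dict:
        return {}

    @property
    def grads(self) -> dict:
        return {}

    def l1_penalty(self) -> float:
        return 0.0


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)  # ceil(n/s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    def __init__(self, filters: int, kernel: int, stride: int = 2,
                 activation: str | None = "relu", l1: float = 0.0, name: str = "conv2d"):
        self.filters, self.kernel, self.stride = filters, kernel, stride
        self.activation, self.l1, self.name = activation, l1, name
        self.W: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self._grads: dict = {}

    def output_shape(self, input_shape):
        h, w, _ = input_shape
        oh = -(-h // self.stride)
        ow = -(-w // self.stride)
        return (oh, ow, self.filters)

    def init_params(self, rng, input_shape):
        h, w, c = input_shape
        self.in_channels = c
        fan_in = self.kernel * self.kernel * c
        fan_out = self.kernel * self.kernel * self.filters
        self.W = _glorot_uniform(rng, fan_in, fan_out, (fan_in, self.filters))
        self.b = np.zeros(self.filters)
        return self.output_shape(input_shape)

    def forward(self, x, training):
        n, h, w, c = x.shape
        k, s = self.kernel, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        # win: (n, oh, ow, c, k, k) -> col rows ordered (k, k, c)
        col = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * c)
        z = col @ self.W + self.b
        self._cache = (col, z, (n, h, w, c), (oh, ow), (pt, pl))
        out = np.maximum(z, 0.0) if self.activation == "relu" else z
        return out.reshape(n, oh, ow, self.filters)

    def backward(self, dout):
        col, z, (n, h, w, c), (oh, ow), (pt, pl) = self._cache
        k, s = self.kernel, self.stride
        dz = dout.reshape(n * oh * ow, self.filters)
        if self.activation == "relu":
            dz = dz * (z > 0)
        dW = col.T @ dz
        if self.l1:
            dW = dW + self.l1 * np.sign(self.W)
        self._grads = {"W": dW, "b": dz.sum(axis=0)}
        dcol = (dz @ self.W.T).reshape(n, oh, ow, k, k, c)
        hp = h + pt + (_same_pad(h, k, s)[2])
        wp = w + pl + (_same_pad(w, k, s)[2])
        dxp = np.zeros((n, hp, wp, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + oh * s : s, j : j + ow * s : s, :] += dcol[:, :, :, i, j, :]
        return dxp[:, pt : pt + h, pl : pl + w, :]

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return self._grads

    def l1_penalty(self):
        return self.l1 * float(np.abs(self.W).sum()) if self.l1 else 0.0


class MaxPool2D(Layer):
    """Max pooling; size 1 / stride 1 is a spatial identity (the default here)."""

    def __init__(self, pool: int = 1, stride: int = 1, name: str = "maxpool2d"):
        self.pool, self.stride, self.name = pool, stride, name

    def output_shape(self, input_shape):
        h, w, c = input_shape
        oh = (h - self.pool) // self.stride + 1
        ow = (w - self.pool) // self.stride + 1
        return (oh, ow, c)

    def forward(self, x, training):
        if self.pool == 1 and self.stride == 1:
            return x
        n, h, w, c = x.shape
        p, s = self.pool, self.stride
        oh = (h - p) // s + 1
        ow = (w - p) // s + 1
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::s, ::s]
        win = win[:, :oh, :ow]  # (n, oh, ow, c, p, p)
        flat = win.reshape(n, oh, ow, c, p * p)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx, (oh, ow))
        return flat.max(axis=-1)

    def backward(self, dout):
        if self.pool == 1 and self.stride == 1:
            return dout
        (n, h, w, c), idx, (oh, ow) = self._cache
        p, s = self.pool, self.stride
        dx = np.zeros((n, h, w, c))
        di, dj = np.unravel_index(idx, (p, p))
        nn, ii, jj, cc = np.meshgrid(
            np.arange(n), np.arange(oh), np.arange(ow), np.arange(c), indexing="ij"
        )
        np.add.at(dx, (nn, ii * s + di, jj * s + dj, cc), dout)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, name: str = "batchnorm"):
        self.name = name
        self._grads: dict = {}

    def init_params(self, rng, input_shape):
        c = input_shape[-1]
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        # Bias-corrected EMAs of batch statistics: stored sums start at zero
        # and are debiased by 1 - momentum^t at inference, so short training
        # runs see the true average statistics instead of the zero/one init.
        self._ema_mean = np.zeros(c)
        self._ema_var = np.zeros(c)
        self._ema_t = np.zeros(1)
        return input_shape

    @property
    def running_mean(self) -> np.ndarray:
        t = self._ema_t[0]
        if t == 0:
            return np.zeros_like(self._ema_mean)
        return self._ema_mean / (1.0 - BN_MOMENTUM**t)

    @property
    def running_var(self) -> np.ndarray:
        t = self._ema_t[0]
        if t == 0:
            return np.ones_like(self._ema_var)
        return self._ema_var / (1.0 - BN_MOMENTUM**t)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self._ema_mean = BN_MOMENTUM * self._ema_mean + (1 - BN_MOMENTUM) * mean
            self._ema_var = BN_MOMENTUM * self._ema_var + (1 - BN_MOMENTUM) * var
            self._ema_t = self._ema_t + 1
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + EPS_BN)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, axes, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self._grads = {
            "gamma": (dout * xhat).sum(axis=axes),
            "beta": dout.sum(axis=axes),
        }
        dxhat = dout * self.gamma
        return inv / m * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )

    @property
    def params(self):
        # EMA state rides along so that saved/loaded weights keep the
        # inference statistics; the optimizer only touches keys with grads.
        return {"gamma": self.gamma, "beta": self.beta,
                "ema_mean": self._ema_mean, "ema_var": self._ema_var,
                "ema_t": self._ema_t}

    @property
    def grads(self):
        return self._grads


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None,
                 name: str = "dropout"):
        self.rate, self.name = rate, name
        self.rng = rng  # set by the network at build time

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = None,
                 l1: float = 0.0, name: str = "dense"):
        self.units, self.activation, self.l1, self.name = units, activation, l1, name
        self._grads: dict = {}

    def output_shape(self, input_shape):
        return (self.units,)

    def init_params(self, rng, input_shape):
        (fan_in,) = input_shape
        self.W = _glorot_uniform(rng, fan_in, self.units, (fan_in, self.units))
        self.b = np.zeros(self.units)
        return (self.units,)

    def forward(self, x, training):
        z = x @ self.W + self.b
        self._cache = (x, z)
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        return z

    def backward(self, dout, preact: bool = False):
        """Backprop; with ``preact=True`` ``dout`` is already dL/dz."""
        x, z = self._cache
        if preact:
            dz = dout
        elif self.activation == "relu":
            dz = dout * (z > 0)
        elif self.activation == "sigmoid":
            p = 1.0 / (1.0 + np.exp(-z))
            dz = dout * p * (1.0 - p)
        else:
            dz = dout
        dW = x.T @ dz
        if self.l1:
            dW = dW + self.l1 * np.sign(self.W)
        self._grads = {"W": dW, "b": dz.sum(axis=0)}
        return dz @ self.W.T

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return self._grads

    def l1_penalty(self):
        return self.l1 * float(np.abs(self.W).sum()) if self.l1 else 0.0


class Adam:
    """Adam with the classical 1/(1 + decay * t) learning-rate schedule."""

    def __init__(self, lr: float = 0.001, decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr0, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: dict = {}
        self.epochs_completed = 0

    @property
    def lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.epochs_completed)

    def step(self, layers) -> None:
        self.t += 1
        lr = self.lr
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for li, layer in enumerate(layers):
            for key, g in layer.grads.items():
                p = layer.params[key]
                sk = (li, key)
                if sk not in self.state:
                    self.state[sk] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[sk]
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[sk] = (m, v)
                p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_loss_and_grad(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on one-hot targets.

    Returns the mean loss over all n*k sigmoid outputs and the gradient of
    that loss with respect to the pre-sigmoid logits (the (p - y)/(n k)
    shortcut, which is exact and numerically stable).
    """
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    dz = (p - y) / p.size
    return loss, dz
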