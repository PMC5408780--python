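"""Minimal NumPy layer primitives with explicit forward/backward passes.

Implements exactly the operators the classifier architecture needs:
3x3 same-padding convolution, batch normalization, ReLU, ceil-mode 2x2 max
pooling, flatten, affine layers, dropout, and an Adam optimizer. Every layer
caches what its backward pass needs; ``backward`` returns the gradient with
respect to the layer input so gradients can be propagated all the way to the
pixels (needed for activation maximization).

All computation is float32. Layers are deterministic given their inputs; the
only stochastic layer (dropout) draws from an rng passed at forward time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Linear",
    "Dropout",
    "Adam",
    "truncated_normal",
    "softmax",
]

DTYPE = np.float32


def truncated_normal(shape, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(0, sd^2) truncated at +/- 2 sd (resampling out-of-range draws)."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > 2.0 * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 2.0 * sd
    return out.astype(DTYPE)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray, k: int, p: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=DTYPE)


class Layer:
    """Base class; subclasses fill ``params``/``grads`` with matching keys."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, via im2col + GEMM."""

    def __init__(self, in_channels: int, out_channels: int, ksize: int,
                 init_sd: float, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ksize = ksize
        self.pad = (ksize - 1) // 2
        # weight stored as (out_channels, in_channels * k * k)
        self.params["W"] = truncated_normal((out_channels, in_channels * ksize * ksize), init_sd, rng)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        cols = _im2col(x, self.ksize, self.pad)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.ksize
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1), dtype=DTYPE).reshape(n * h * w, self.out_channels)
        self.grads["W"] = (dflat.T @ cols).astype(DTYPE)
        self.grads["b"] = dflat.sum(axis=0).astype(DTYPE)
        # d(input) is the full correlation of dout with the spatially flipped,
        # channel-transposed kernel: one im2col + one GEMM instead of col2im
        w_t = self.params["W"].reshape(self.out_channels, c, k, k)
        w_t = np.ascontiguousarray(
            w_t.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]).reshape(c, self.out_channels * k * k)
        dcols = _im2col(dout, k, self.pad)
        dx = dcols @ w_t.T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class BatchNorm(Layer):
    """Batch normalization over (N,) for 2-D inputs or (N, H, W) per channel.

    Training mode uses batch statistics and updates running estimates with
    ``momentum``; evaluation mode applies the running affine transform.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_features, dtype=DTYPE)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _bcast(self, v, ndim):
        return v if ndim == 2 else v[:, None, None]

    def forward(self, x, training=False):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bcast(mean, x.ndim)) * self._bcast(inv_sd, x.ndim)
        self._cache = (xhat, inv_sd, training, x.shape)
        g = self._bcast(self.params["gamma"], x.ndim)
        b = self._bcast(self.params["beta"], x.ndim)
        return (g * xhat + b).astype(DTYPE)

    def backward(self, dout):
        xhat, inv_sd, training, shape = self._cache
        axes = self._axes(dout)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=axes).astype(DTYPE)
        g_inv = self._bcast(self.params["gamma"] * inv_sd, dout.ndim)
        if not training:
            return (dout * g_inv).astype(DTYPE)
        m = dout.size // dout.shape[1] if dout.ndim == 4 else dout.shape[0]
        dxhat = dout * self._bcast(self.params["gamma"], dout.ndim)
        term = (dxhat - self._bcast(dxhat.mean(axis=axes), dout.ndim)
                - xhat * self._bcast((dxhat * xhat).mean(axis=axes), dout.ndim))
        return (term * self._bcast(inv_sd, dout.ndim)).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, dout):
        return np.where(self._mask, dout, 0).astype(DTYPE)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd edges padded with -inf)."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        xp = x
        if h % 2 or w % 2:
            xp = np.full((n, c, ho * 2, wo * 2), -np.inf, dtype=DTYPE)
            xp[:, :, :h, :w] = x
        blocks = xp.reshape(n, c, ho, 2, wo, 2)
        out = blocks.max(axis=(3, 5))
        self._cache = (blocks == out[:, :, :, None, :, None], (h, w))
        return out.astype(DTYPE)

    def backward(self, dout):
        mask, (h, w) = self._cache
        n, c, ho, _, wo, _ = mask.shape
        # split ties evenly so the gradient mass is conserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        return d.reshape(n, c, ho * 2, wo * 2)[:, :, :h, :w].astype(DTYPE)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, init_sd: float, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = truncated_normal((n_in, n_out), init_sd, rng)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(DTYPE)
        self.grads["b"] = dout.sum(axis=0).astype(DTYPE)
        return (dout @ self.params["W"].T).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Adam:
    """Adam over a list of layers; learning rate supplied per step."""

    def __init__(self, layers, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self, lr: float) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= (lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)).astype(DTYPE)
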