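"""Minimal CPU convolutional-network engine.

A small, self-contained layer framework (NHWC float32 tensors, im2col
convolutions, manual backprop, Adam) sized for training compact
encoder-decoder segmentation networks on synthetic data with a single CPU.
Each layer caches what its backward pass needs; ``forward`` takes a
``training`` flag so batch-norm and dropout switch between train and
inference behaviour.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class: trainable layers override ``params``/``grads``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patches with same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * h * w, k * k * x.shape[3]
    )


class Conv2d(Layer):
    """3x3 (or 1x1) same-padding convolution, stride 1, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        scale = np.sqrt(2.0 / (k * k * in_ch))
        self.w = (rng.standard_normal((k * k * in_ch, out_ch)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training=False):
        self._x = x
        n, h, w_, _ = x.shape
        if self.k == 1:
            out = x.reshape(-1, self.in_ch) @ self.w + self.b
        else:
            out = _im2col(x, self.k) @ self.w + self.b
        return out.reshape(n, h, w_, self.out_ch)

    def backward(self, dout):
        x = self._x
        n, h, w_, _ = x.shape
        dflat = dout.reshape(-1, self.out_ch)
        self.db[:] = dflat.sum(axis=0)
        if self.k == 1:
            self.dw[:] = x.reshape(-1, self.in_ch).T @ dflat
            return (dflat @ self.w.T).reshape(x.shape)
        self.dw[:] = _im2col(x, self.k).T @ dflat
        # dx = full correlation of dout with the spatially flipped kernel
        wk = self.w.reshape(self.k, self.k, self.in_ch, self.out_ch)
        wk = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.in_ch)
        cols = _im2col(dout, self.k)
        return (cols @ wk).reshape(x.shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (N, H, W) with running stats."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        if training:
            self._cache = (xhat, std)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout):
        xhat, std = self._cache
        self.dgamma[:] = (dout * xhat).sum(axis=(0, 1, 2))
        self.dbeta[:] = dout.sum(axis=(0, 1, 2))
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dxhat = dout * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / m
        ) / std
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling; ties share the gradient equally."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._x_shape = x.shape
        self._mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout):
        n, h, w, c = self._x_shape
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        dxr = self._mask * (dout[:, :, None, :, None, :] / counts)
        return dxr.reshape(n, h, w, c).astype(np.float32)


class UpsampleNearest2(Layer):
    def forward(self, x, training=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        return dout.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, fraction: float, rng: np.random.Generator):
        self.fraction = fraction
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.fraction <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.fraction
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    """Adaptive-moment optimiser over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
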