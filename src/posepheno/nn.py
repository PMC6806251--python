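"""Minimal CPU neural-network layers in numpy.

The action classifier is small (four 3×3 convolutions, global average
pooling, one affine layer), so the layers are implemented directly on
BLAS matmuls: a 3×3 convolution is nine strided-view matmuls
(shift-and-add), which avoids im2col copies and keeps both passes
cache-friendly.  Internally activations are channels-last ``(N, H, W, C)``
float32; the public model API converts from the channels-first map layout
at the boundary.

Determinism: weight initialisation and dropout masks are drawn from a
single ``numpy.random.Generator`` owned by the model, so a fixed seed
reproduces training exactly on the same BLAS build.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .types import ValidationError


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for 'same' padding."""
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; gradients are filled by backward."""
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3×3 (or k×k) convolution, 'same' padding, stride 1 or 2.

    Lowered to a single BLAS sgemm per pass via im2col: the padded input
    is gathered once into a contiguous ``(N·oh·ow, k·k·c_in)`` patch
    matrix, multiplied against the ``(k·k·c_in, c_out)`` filter matrix.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel, self.stride = kernel, stride
        fan_in = kernel * kernel * c_in
        std = math.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.W = rng.normal(0.0, std, size=(kernel, kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: Optional[tuple] = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _geometry(self, h: int, w: int):
        k, s = self.kernel, self.stride
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        return oh, ow, (pt, pb), (pl, pr)

    def _im2col(self, x_pad: np.ndarray, oh: int, ow: int) -> np.ndarray:
        k, s = self.kernel, self.stride
        # (N, H', W', C, k, k) windows -> strided sample -> (N, oh, ow, k, k, C)
        win = np.lib.stride_tricks.sliding_window_view(x_pad, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s][:, :oh, :ow]
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        n = x_pad.shape[0]
        return col.reshape(n * oh * ow, k * k * x_pad.shape[-1])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c_in = x.shape
        k, s = self.kernel, self.stride
        oh, ow, (pt, pb), (pl, pr) = self._geometry(h, w)
        x_pad = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        col = self._im2col(x_pad, oh, ow)
        w_mat = self.W.reshape(k * k * c_in, -1)
        out = (col @ w_mat + self.b).reshape(n, oh, ow, -1)
        if train:
            self._cache = (col, x_pad.shape, x.shape, (pt, pl), (oh, ow))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, pad_shape, x_shape, (pt, pl), (oh, ow) = self._cache
        n, h, w, c_in = x_shape
        k, s = self.kernel, self.stride
        c_out = self.W.shape[-1]
        dy_mat = dy.reshape(n * oh * ow, c_out)
        self.db[...] = dy_mat.sum(axis=0)
        self.dW[...] = (col.T @ dy_mat).reshape(self.W.shape)
        dcol = (dy_mat @ self.W.reshape(-1, c_out).T).reshape(n, oh, ow, k, k, c_in)
        dx_pad = np.zeros(pad_shape, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                rows = slice(di, di + s * (oh - 1) + 1, s)
                cols = slice(dj, dj + s * (ow - 1) + 1, s)
                dx_pad[:, rows, cols, :] += dcol[:, :, :, di, dj, :]
        self._cache = None
        return dx_pad[:, pt : pt + h, pl : pl + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        # exponential moving averages with bias correction, so eval-mode
        # statistics are sensible even after only a few training batches
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.zeros(channels, dtype=np.float32)
        self.updates = 0
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def eval_stats(self) -> tuple[np.ndarray, np.ndarray]:
        if self.updates == 0:
            return self.running_mean, np.ones_like(self.running_var)
        corr = 1.0 - self.momentum**self.updates
        return self.running_mean / corr, self.running_var / corr

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.updates += 1
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.eval_stats()
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dx = (
            self.gamma
            * inv_std
            / m
            * (m * dy - self.dbeta - xhat * self.dgamma)
        )
        self._cache = None
        return dx.astype(np.float32)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not (0.0 <= p < 1.0):
            raise ValidationError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (
            self.rng.random(x.shape, dtype=np.float32) < keep
        ).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return dy
        return dy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(
            np.float32
        )


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, std, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam optimiser over a list of (param, grad) pairs."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
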