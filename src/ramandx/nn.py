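"""Minimal 1-D neural-network engine on numpy.

Implements exactly the layer zoo the spectral models need — 1-D
convolution, transposed convolution, batch normalization, average pooling,
dense layers, ReLU/LeakyReLU — with hand-written backward passes and an
Adam optimizer.  All layers operate on float32 arrays of shape
``(batch, channels, length)`` (dense layers on ``(batch, features)``).
Backward passes are verified against finite differences in the test
suite.

Shape conventions follow the usual output-size formulas:

* convolution: ``o = (i + 2p - k) / s + 1`` (must divide exactly),
* transposed convolution: ``o = (i - 1) s - 2 p + k``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base layer: parameters are (array, grad) pairs updated by Adam."""

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# size formulas
# ---------------------------------------------------------------------------


def conv_output_size(i: int, s: int, p: int, k: int) -> int:
    """``o = (i + 2p - k)/s + 1``; raises if not exactly divisible or <= 0."""
    num = i + 2 * p - k
    if num < 0 or num % s != 0:
        raise ValueError(
            f"conv size (i={i}, s={s}, p={p}, k={k}): (i+2p-k) not divisible by s"
        )
    o = num // s + 1
    if o <= 0:
        raise ValueError(f"conv size (i={i}, s={s}, p={p}, k={k}) gives o={o}")
    return o


def transposed_conv_output_size(i: int, s: int, p: int, k: int) -> int:
    """``o = (i - 1) s - 2p + k``; raises if the result is not positive."""
    o = (i - 1) * s - 2 * p + k
    if o <= 0:
        raise ValueError(f"transposed conv (i={i}, s={s}, p={p}, k={k}) gives o={o}")
    return o


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv1d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        fan_in = in_ch * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel)) / np.sqrt(fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, L = x.shape
        Lo = conv_output_size(L, self.s, self.p, self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p))) if self.p else x
        sw = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.s, :]
        cols = np.ascontiguousarray(sw.transpose(0, 2, 1, 3)).reshape(
            n * Lo, c * self.k
        )
        self._cols, self._shape, self._Lo = cols, x.shape, Lo
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        return out.reshape(n, Lo, self.out_ch).transpose(0, 2, 1)

    def backward(self, grad_out):
        n, c, L = self._shape
        Lo = self._Lo
        g = np.ascontiguousarray(grad_out.transpose(0, 2, 1), dtype=DTYPE).reshape(
            n * Lo, self.out_ch
        )
        self.gW[...] = (g.T @ self._cols).reshape(self.W.shape)
        self.gb[...] = g.sum(axis=0)
        gcols = (g @ self.W.reshape(self.out_ch, -1)).reshape(n, Lo, c, self.k)
        gcols = gcols.transpose(0, 2, 1, 3)  # (n, c, Lo, k)
        gxp = np.zeros((n, c, L + 2 * self.p), dtype=DTYPE)
        span = (Lo - 1) * self.s + 1
        for j in range(self.k):
            gxp[:, :, j : j + span : self.s] += gcols[:, :, :, j]
        return gxp[:, :, self.p : self.p + L] if self.p else gxp


class ConvTranspose1d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        fan_in = in_ch * kernel
        self.W = (rng.standard_normal((in_ch, out_ch, kernel)) / np.sqrt(fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, Li = x.shape
        Lo = transposed_conv_output_size(Li, self.s, self.p, self.k)
        self._x = x
        t = x.transpose(0, 2, 1).reshape(n * Li, c) @ self.W.reshape(c, -1)
        t = t.reshape(n, Li, self.out_ch, self.k)
        full = np.zeros((n, self.out_ch, (Li - 1) * self.s + self.k), dtype=DTYPE)
        span = (Li - 1) * self.s + 1
        for j in range(self.k):
            full[:, :, j : j + span : self.s] += t[:, :, :, j].transpose(0, 2, 1)
        out = full[:, :, self.p : self.p + Lo]
        return out + self.b[None, :, None]

    def backward(self, grad_out):
        x = self._x
        n, c, Li = x.shape
        Lo = grad_out.shape[2]
        g_full = np.zeros((n, self.out_ch, (Li - 1) * self.s + self.k), dtype=DTYPE)
        g_full[:, :, self.p : self.p + Lo] = grad_out
        span = (Li - 1) * self.s + 1
        gt = np.empty((n, Li, self.out_ch, self.k), dtype=DTYPE)
        for j in range(self.k):
            gt[:, :, :, j] = g_full[:, :, j : j + span : self.s].transpose(0, 2, 1)
        gt2 = gt.reshape(n * Li, -1)
        xm = x.transpose(0, 2, 1).reshape(n * Li, c)
        self.gW[...] = (xm.T @ gt2).reshape(self.W.shape)
        self.gb[...] = grad_out.sum(axis=(0, 2))
        gx = (gt2 @ self.W.reshape(c, -1).T).reshape(n, Li, c)
        return gx.transpose(0, 2, 1)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if train:
            mean = x.mean(axis=(0, 2))
            var = np.einsum("ncl,ncl->c", x, x) / (x.shape[0] * x.shape[2]) - mean**2
            var = np.maximum(var, 0.0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        a = self.gamma * inv
        b = self.beta - mean.astype(DTYPE) * a
        self._x, self._mean, self._inv = x, mean.astype(DTYPE), inv
        return x * a[None, :, None] + b[None, :, None]

    def backward(self, grad_out):
        inv = self._inv
        xhat = (self._x - self._mean[None, :, None]) * inv[None, :, None]
        self.ggamma[...] = (grad_out * xhat).sum(axis=(0, 2))
        self.gbeta[...] = grad_out.sum(axis=(0, 2))
        gxhat = grad_out * self.gamma[None, :, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        ) * inv[None, :, None]
        return gx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, 0).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, self.slope * grad_out).astype(DTYPE)


class AvgPool1d(Layer):
    """Average pooling, no padding: ``o = floor((L - size)/stride) + 1``."""

    def __init__(self, size: int = 2, stride: int = 2):
        self.size, self.stride = size, stride

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, L = x.shape
        Lo = (L - self.size) // self.stride + 1
        if Lo < 1:
            raise ValueError(f"input length {L} too short for pooling")
        self._L = L
        if self.size == self.stride:  # non-overlapping: cheap reshape path
            r = x[:, :, : Lo * self.size].reshape(n, c, Lo, self.size)
            out = r[:, :, :, 0].copy()
            for j in range(1, self.size):
                out += r[:, :, :, j]
            out *= DTYPE(1.0 / self.size)
            return out
        sw = sliding_window_view(x, self.size, axis=2)[:, :, :: self.stride, :]
        return sw.mean(axis=3).astype(DTYPE)

    def backward(self, grad_out):
        n, c, Lo = grad_out.shape
        gx = np.zeros((n, c, self._L), dtype=DTYPE)
        g = grad_out / self.size
        span = (Lo - 1) * self.stride + 1
        for j in range(self.size):
            gx[:, :, j : j + span : self.stride] += g
        return gx


class Flatten(Layer):
    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return np.ascontiguousarray(x, dtype=DTYPE).reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((in_f, out_f)) / np.sqrt(in_f)).astype(DTYPE)
        self.b = np.zeros(out_f, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x, train: bool = True):
        self._x = np.ascontiguousarray(x, dtype=DTYPE)
        return self._x @ self.W + self.b

    def backward(self, grad_out):
        grad_out = grad_out.astype(DTYPE)
        self.gW[...] = self._x.T @ grad_out
        self.gb[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted mean binary cross-entropy on logits; numerically stable.

    ``weights`` (optional, per sample) rescale each term; the loss is the
    weighted sum divided by the number of samples.
    """
    z = logits.astype(np.float64).ravel()
    t = targets.astype(np.float64).ravel()
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = (p - t) / z.size
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64).ravel()
        loss = loss * w
        grad = grad * w
    return float(loss.sum() / z.size), grad.astype(DTYPE).reshape(logits.shape)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adaptive-moment estimation with configurable decay factors."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)
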