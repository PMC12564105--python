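"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the operations the artifact classifier needs — 1-D
convolution (same padding), batch normalization, ReLU, max pooling,
GAP+GMP channel attention, fully connected layers, dropout, and a fused
softmax/cross-entropy head — together with an Adam optimizer.  All
computation is float32 and flows from explicitly passed generators, so
training is bit-reproducible on a single device.

Convolutional-stage tensors are channels-last, ``(batch, length,
channels)``: the im2col patch matrix is then a contiguous reshape away
from one GEMM per layer, with no transposes anywhere on the hot path.
After flattening, tensors are ``(batch, features)``.  Gradients are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution via im2col and one GEMM per batch."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size
        self.W = _uniform_init(rng, (kernel_size * in_channels, out_channels), fan_in)
        self.b = _uniform_init(rng, (out_channels,), fan_in)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = np.empty((B, L, self.k, C), dtype=DTYPE)
        for i in range(self.k):
            cols[:, :, i, :] = xp[:, i : i + L, :]
        self.cols = cols
        y = cols.reshape(B * L, self.k * C) @ self.W + self.b
        return y.reshape(B, L, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, _ = dout.shape
        dy = dout.reshape(B * L, self.cout)
        cols2d = self.cols.reshape(B * L, self.k * self.cin)
        self.dW[...] = cols2d.T @ dy
        self.db[...] = dy.sum(axis=0)
        dcols = (dy @ self.W.T).reshape(B, L, self.k, self.cin)
        p = self.k // 2
        dxp = np.zeros((B, L + 2 * p, self.cin), dtype=DTYPE)
        for i in range(self.k):
            dxp[:, i : i + L, :] += dcols[:, :, i, :]
        return dxp[:, p : p + L, :]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time, with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self.xhat = (x - mean) * self.inv_std
        return self.gamma * self.xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dgamma[...] = (dout * self.xhat).sum(axis=(0, 1))
        self.dbeta[...] = dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma
        # batch-statistics backward (training-mode normalization)
        term2 = dxhat.mean(axis=(0, 1))
        term3 = self.xhat * (dxhat * self.xhat).mean(axis=(0, 1))
        return self.inv_std * (dxhat - term2 - term3)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along time; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.pool
        self.in_len = L
        xv = x[:, : Lo * self.pool, :].reshape(B, Lo, self.pool, C)
        self.arg = xv.argmax(axis=2)
        return xv.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, Lo, C = dout.shape
        dx = np.zeros((B, Lo, self.pool, C), dtype=DTYPE)
        bi, li, ci = np.ogrid[:B, :Lo, :C]
        dx[bi, li, self.arg, ci] = dout
        dx = dx.reshape(B, Lo * self.pool, C)
        if Lo * self.pool < self.in_len:
            dx = np.pad(dx, ((0, 0), (0, self.in_len - Lo * self.pool), (0, 0)))
        return dx


class ChannelAttention(Layer):
    """GAP+GMP channel gate.

    Global average and max pooling over time give two C-vectors; their
    concatenation is linearly mapped (2C -> C, the 1x1-convolution of the
    pooled descriptor) and squashed by a sigmoid into per-channel weights
    in (0, 1) that rescale the feature map.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.C = channels
        self.W = _uniform_init(rng, (2 * channels, channels), 2 * channels)
        self.b = _uniform_init(rng, (channels,), 2 * channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x  # (B, L, C)
        B, L, C = x.shape
        g_avg = x.mean(axis=1)
        self.argmax = x.argmax(axis=1)  # (B, C)
        bi, ci = np.ogrid[:B, :C]
        g_max = x[bi, self.argmax, ci]
        self.G = np.concatenate([g_avg, g_max], axis=1)
        z = self.G @ self.W + self.b
        self.A = 1.0 / (1.0 + np.exp(-z))  # (B, C)
        return x * self.A[:, None, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = dout.shape
        dx = dout * self.A[:, None, :]
        dA = (dout * self.x).sum(axis=1)
        dz = dA * self.A * (1.0 - self.A)
        self.dW[...] = self.G.T @ dz
        self.db[...] = dz.sum(axis=0)
        dG = dz @ self.W.T
        dx += dG[:, None, :C] / L  # through GAP
        bi, ci = np.ogrid[:B, :C]
        dx[bi, self.argmax, ci] += dG[:, C:]  # through GMP
        return dx

    def attention_map(self, x: np.ndarray) -> np.ndarray:
        """Channel weights for ``x`` (B, L, C) without mutating cached state."""
        G = np.concatenate([x.mean(axis=1), x.max(axis=1)], axis=1)
        return 1.0 / (1.0 + np.exp(-(G @ self.W + self.b)))


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _uniform_init(rng, (in_features, out_features), in_features)
        self.b = _uniform_init(rng, (out_features,), in_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self.x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self.mask is None else dout * self.mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean multiclass cross-entropy ``-mean(log p[label])``."""
    n = labels.shape[0]
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy w.r.t. the logits."""
    n = labels.shape[0]
    g = probs.copy()
    g[np.arange(n), labels] -= 1.0
    return (g / n).astype(DTYPE)


class Adam:
    """Adaptive-moment-estimation optimizer over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
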