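"""Minimal NumPy neural-network engine: 1-D convolution, max-pooling,
dropout, dense layers, softmax cross-entropy, and an Adam optimizer.

Only what the three-branch classifier needs — valid-mode convolutions via
im2col + BLAS matmul, non-overlapping pooling, inverted dropout.  All
randomness (init, dropout) flows from a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "ReLU", "MaxPool1D", "Dropout", "Flatten", "Dense",
           "Sequential", "Adam", "softmax", "softmax_cross_entropy"]


class Layer:
    """Base layer: forward/backward plus (params, grads) exposure."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Valid-mode 1-D convolution over (batch, length, channels) input."""

    def __init__(self, in_channels: int, n_filters: int, kernel_len: int,
                 rng: np.random.Generator):
        self.kernel_len = kernel_len
        self.in_channels = in_channels
        self.n_filters = n_filters
        fan_in = kernel_len * in_channels
        self.W = _glorot_uniform(rng, fan_in, n_filters, (fan_in, n_filters))
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        K = self.kernel_len
        # (B, L_out, C, K) view -> (B, L_out, K*C) with K-major ordering
        view = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)
        col = view.transpose(0, 1, 3, 2).reshape(B, L - K + 1, K * C)
        self._col = col
        self._in_shape = x.shape
        return col @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, L_out, F = grad.shape
        K, C = self.kernel_len, self.in_channels
        col2 = self._col.reshape(-1, K * C)
        g2 = grad.reshape(-1, F)
        self.dW[...] = col2.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcol = (g2 @ self.W.T).reshape(B, L_out, K, C)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        for k in range(K):
            dx[:, k : k + L_out, :] += dcol[:, :, k, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    """max(x, alpha*x); the small negative slope keeps gradient flowing
    through units that would otherwise die early in training."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; trailing samples
    that do not fill a full pool are dropped."""

    def __init__(self, pool_len: int):
        self.pool_len = pool_len

    def forward(self, x, training):
        B, L, F = x.shape
        p = self.pool_len
        L_out = L // p
        blocks = x[:, : L_out * p, :].reshape(B, L_out, p, F)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, grad):
        B, L_out, F = grad.shape
        p = self.pool_len
        dblocks = np.zeros((B, L_out, p, F), dtype=grad.dtype)
        bi, li, fi = np.ogrid[:B, :L_out, :F]
        dblocks[bi, li, self._argmax, fi] = grad
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : L_out * p, :] = dblocks.reshape(B, L_out * p, F)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _glorot_uniform(rng, in_features, out_features,
                                 (in_features, out_features))
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable row-wise softmax."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-(onehot * np.log(probs + eps)).sum() / n)
    return loss, (probs - onehot) / n


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
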