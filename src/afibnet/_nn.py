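"""Minimal 1-D convolutional network engine on numpy.

Implements exactly the layer vocabulary the classifier needs — valid
1-D convolution (stride 1), ReLU, max-pooling (size 2, stride 2),
flatten, dense, and sigmoid/softmax heads — with reverse-mode
gradients, sample-weighted cross-entropy losses, and the Adam update
rule.  Arrays are float32 throughout; batches are (batch, length,
channels) for convolutional layers and (batch, features) after
flatten.

Convolution uses an im2col lowering to a single matmul per layer;
its backward pass was verified against central finite differences
(see the gradient-check tests).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense",
    "Sequential", "Adam", "weighted_bce", "weighted_cce",
]

_F = np.float32


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # He (Kaiming) fan-in-scaled uniform: the standard scheme for
    # ReLU-activated stacks, preserving activation variance with depth.
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(_F)


class Layer:
    params: list
    grads: list

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1-D convolution, kernel width ``k``, stride 1, bias included.

    Weight shape (out_channels, in_channels, k); output length L - k + 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * kernel
        self.W = _he_uniform(rng, (out_channels, in_channels, kernel), fan_in)
        self.b = np.zeros(out_channels, dtype=_F)
        self.params = [self.W, self.b]
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, L, C). Lower to columns (B, L', C*k) and matmul.
        B, L, C = x.shape
        Lout = L - self.k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)  # (B, L', C, k)
        self._cols = cols.reshape(B, Lout, C * self.k)
        Wm = self.W.transpose(1, 2, 0).reshape(C * self.k, self.out_channels)
        self._x_shape = x.shape
        return self._cols @ Wm + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, L, C = self._x_shape
        Lout = L - self.k + 1
        g2 = grad.reshape(-1, self.out_channels)
        cols2 = self._cols.reshape(-1, C * self.k)
        dWm = cols2.T @ g2  # (C*k, out)
        self.dW[...] = dWm.reshape(C, self.k, self.out_channels).transpose(2, 0, 1)
        self.db[...] = g2.sum(axis=0)
        # Scatter dcols back onto the input: k shifted additions.
        Wm = self.W.transpose(1, 2, 0).reshape(C * self.k, self.out_channels)
        dcols = (grad @ Wm.T).reshape(B, Lout, C, self.k)
        dx = np.zeros((B, L, C), dtype=_F)
        for j in range(self.k):
            dx[:, j:j + Lout, :] += dcols[:, :, :, j]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Max pooling, size 2 / stride 2; an odd trailing sample is dropped
    (floor semantics, matching L -> L // 2)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        Lout = L // 2
        xv = x[:, :2 * Lout, :].reshape(B, Lout, 2, C)
        self._argmax = xv.argmax(axis=2)  # (B, Lout, C)
        self._in_shape = x.shape
        return xv.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        Lout = L // 2
        dx = np.zeros((B, Lout, 2, C), dtype=_F)
        b_idx, l_idx, c_idx = np.ogrid[:B, :Lout, :C]
        dx[b_idx, l_idx, self._argmax, c_idx] = grad
        out = np.zeros((B, L, C), dtype=_F)
        out[:, :2 * Lout, :] = dx.reshape(B, 2 * Lout, C)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _he_uniform(rng, (in_features, units), in_features)
        self.b = np.zeros(units, dtype=_F)
        self.params = [self.W, self.b]
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    """A feed-forward stack ending in raw logits; the output nonlinearity
    lives in the loss/prediction helpers for numerical stability."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=_F)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, grad: np.ndarray) -> None:
        g = grad.astype(_F)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z.astype(np.float64))
    return e / e.sum(axis=1, keepdims=True)


def weighted_bce(logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
    """Weighted binary cross-entropy on a single sigmoid logit.

    Returns (mean weighted loss, gradient wrt logits).
    """
    z = logits.reshape(-1)
    p = _sigmoid(z)
    w = sample_weight
    # log(1+exp(-|z|)) form is stable for both signs.
    ce = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0) - y * z
    loss = float(np.mean(w * ce))
    grad = (w * (p - y) / len(z)).reshape(logits.shape)
    return loss, grad


def weighted_cce(logits: np.ndarray, y_index: np.ndarray, sample_weight: np.ndarray):
    """Weighted categorical cross-entropy on softmax logits.

    ``y_index`` holds integer class indices.
    """
    p = _softmax(logits)
    n = len(y_index)
    w = sample_weight
    ce = -np.log(np.clip(p[np.arange(n), y_index], 1e-12, None))
    loss = float(np.mean(w * ce))
    grad = p.copy()
    grad[np.arange(n), y_index] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
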