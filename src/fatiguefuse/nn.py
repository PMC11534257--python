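"""Minimal NumPy neural-network engine for the classifier.

Implements exactly the layers the fatigue model needs — 1-D
convolution (same padding, stride 1), ReLU, squeeze-and-excitation
blocks, parameter-free simAM weighting, flatten, dense — with manual
reverse-mode gradients and an Adam optimizer.  Everything is seeded
and single-threaded-deterministic.

Batches are ``(batch, channels, length)`` float32 arrays.  In the simAM
layer the attention weights are treated as constants during the
backward pass (gradients flow through the multiplicative path only).
"""

from __future__ import annotations

import numpy as np

from .attention import SENetParams

DTYPE = np.float32


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: forward caches what backward needs; params() lists
    (weight, gradient) pairs updated in place by the optimizer."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    @property
    def n_params(self) -> int:
        return sum(w.size for w, _ in self.params())


class Conv1D(Layer):
    """k-tap 1-D convolution, stride 1, right-zero-padded to keep length."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel
        self.W = (rng.standard_normal((out_channels, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        xp = np.concatenate([x, np.zeros((b, c, self.kernel - 1), dtype=x.dtype)], axis=2)
        cols = [xp[:, :, j : j + t] for j in range(self.kernel)]
        return np.concatenate(cols, axis=1)  # (B, C*k, T)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        y = np.einsum("of,bft->bot", self.W, self._cols, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, t = self._x_shape
        self.dW += np.einsum("bot,bft->of", dy, self._cols, optimize=True)
        self.db += dy.sum(axis=(0, 2))
        dcols = np.einsum("of,bot->bft", self.W, dy, optimize=True)
        dxp = np.zeros((b, c, t + self.kernel - 1), dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, :, j : j + t] += dcols[:, j * c : (j + 1) * c, :]
        return dxp[:, :, :t]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class SENetBlock(Layer):
    """Squeeze-and-excitation gate over the channel axis.

    Reduced width is ``channels // r`` (floor; at least 1).  No bias
    terms, so the block carries exactly ``2 * channels * (channels//r)``
    trainable parameters.
    """

    def __init__(self, channels: int, r: int, rng: np.random.Generator):
        if r < 1 or r > channels:
            raise ValueError("reduction factor must satisfy 1 <= r <= channels")
        p = SENetParams.init(channels, r, rng)
        self.W1 = p.W1.astype(DTYPE)
        self.W2 = p.W2.astype(DTYPE)
        self.r = r
        self.dW1 = np.zeros_like(self.W1)
        self.dW2 = np.zeros_like(self.W2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._xsq = x.mean(axis=2)  # (B, C)
        self._z1 = self._xsq @ self.W1.T
        self._a = np.maximum(self._z1, 0.0)
        self._s = _sigmoid(self._a @ self.W2.T)  # (B, C)
        return self._s[:, :, None] * x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        t = self._x.shape[2]
        dx = self._s[:, :, None] * dy
        ds = np.einsum("bct,bct->bc", dy, self._x, optimize=True)
        dz2 = ds * self._s * (1.0 - self._s)
        self.dW2 += dz2.T @ self._a
        da = dz2 @ self.W2
        dz1 = da * (self._z1 > 0)
        self.dW1 += dz1.T @ self._xsq
        dxsq = dz1 @ self.W1
        return dx + dxsq[:, :, None] / t

    def params(self):
        return [(self.W1, self.dW1), (self.W2, self.dW2)]


class SimAM(Layer):
    """Parameter-free neuron attention: y = sigmoid(1/e*) * x.

    e* is the closed-form minimum energy with pooled channel statistics.
    The weights are held fixed during backprop.
    """

    def __init__(self, lam: float = 1e-4):
        if lam <= 0:
            raise ValueError("lambda must be positive")
        self.lam = lam

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        e = 4.0 * (var + self.lam) / ((x - mu) ** 2 + 2.0 * var + 2.0 * self.lam)
        self._w = _sigmoid(1.0 / e)
        return self._w * x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self._w * dy


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu_init: bool = True):
        scale = np.sqrt(2.0 / n_in) if relu_init else np.sqrt(1.0 / n_in)
        self.W = (rng.standard_normal((n_out, n_in)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Sequential:
    """Plain layer stack with forward/backward and parameter accounting."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _, g in layer.params():
                g[...] = 0.0

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(weights) != len(own):
            raise ValueError("weight list does not match architecture")
        for (w, _), new in zip(own, weights):
            w[...] = new


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=1)))


class Adam:
    """Adam with the usual bias correction; state per parameter array."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            w -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
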