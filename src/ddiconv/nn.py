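"""Minimal NumPy neural-network engine: layers, activations, Adam.

Implements exactly the pieces the fused convolutional classifier needs —
1-D valid convolution, dense layers, batch normalization, inverted dropout,
softmax cross-entropy — with hand-written backward passes.  All arithmetic
is float32.  Each layer exposes ``forward(x, training)``, ``backward(dout)``
and parameter/gradient lists consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# activations


class Activation:
    """Element-wise activation; shape-agnostic."""

    name = "linear"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = x
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Tanh(Activation):
    name = "tanh"

    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y * self._y)


class Relu(Activation):
    name = "relu"

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dout):
        return dout * self._mask


class Elu(Activation):
    name = "elu"

    def __init__(self, alpha: float = 1.0):
        self.alpha = DTYPE(alpha)

    def forward(self, x, training=False):
        self._neg = x < 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0).astype(DTYPE, copy=False)
        return np.where(self._neg, self.alpha * self._expm1, x).astype(DTYPE, copy=False)

    def backward(self, dout):
        grad = np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)
        return dout * grad


class Sigmoid(Activation):
    name = "sigmoid"

    def forward(self, x, training=False):
        # stable logistic
        self._y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(DTYPE, copy=False)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


ACTIVATIONS = {"linear": Activation, "tanh": Tanh, "relu": Relu, "elu": Elu, "sigmoid": Sigmoid}


def make_activation(name: str) -> Activation:
    try:
        return ACTIVATIONS[name]()
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}") from None


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


# ---------------------------------------------------------------------------
# parameterized layers


class Conv1D:
    """Valid 1-D convolution, stride 1, single input channel.

    Input ``(n, L)`` -> output ``(n, L - k + 1, filters)``.
    """

    def __init__(self, kernel: int, filters: int, rng: np.random.Generator):
        if kernel < 1 or filters < 1:
            raise ValueError("kernel and filter counts must be positive")
        self.kernel = kernel
        self.filters = filters
        self.w = glorot_uniform(rng, kernel, filters, (kernel, filters))
        self.b = np.zeros(filters, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] < self.kernel:
            raise ValueError(f"kernel size {self.kernel} exceeds input length {x.shape[1]}")
        self._windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        return self._windows @ self.w + self.b

    def backward(self, dout: np.ndarray) -> None:
        self.dw[...] = np.einsum("nlk,nlf->kf", self._windows, dout)
        self.db[...] = dout.sum(axis=(0, 1))
        return None  # always the first layer; input gradient unused

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Flatten:
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []

    def grads(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class BatchNorm:
    """Batch normalization over the feature axis of 2-D input."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim, dtype=DTYPE)
        self.beta = np.zeros(dim, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mean) * self._inv_std).astype(DTYPE)
        self._training_batch = training and x.shape[0] > 1
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=0)
        self.dbeta[...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        if not self._training_batch:
            return dxhat * self._inv_std
        n = dout.shape[0]
        # standard batch-norm backward through batch statistics
        return (
            self._inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))
        ).astype(DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient w.r.t. logits.

    ``y`` is an integer class vector.
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


def cross_entropy_from_proba(proba: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy given probabilities directly (averaged-head fusion)."""
    n = proba.shape[0]
    eps = 1e-12
    loss = -np.log(proba[np.arange(n), y] + eps).mean()
    grad = np.zeros_like(proba, dtype=np.float64)
    grad[np.arange(n), y] = -1.0 / (proba[np.arange(n), y] + eps) / n
    return float(loss), grad


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
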