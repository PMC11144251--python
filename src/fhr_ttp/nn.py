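"""A small numpy neural-network engine for 1-D convolutional classifiers.

Implements exactly the layer set the package's models need -- 1-D
convolution with 'same' padding, batch normalisation, max pooling, global
average pooling, dense layers, ReLU, dropout -- with hand-written forward
and backward passes and an Adam optimiser. Arrays are ``(batch, time,
channels)`` for sequence layers and ``(batch, features)`` after pooling or
flattening. Every layer's gradient is verified against finite differences
in the test suite.

The engine is deliberately minimal: no autograd graph, no GPU, float64
arithmetic. Layers cache what their backward pass needs during a training
forward; inference passes (``training=False``) use running batch-norm
statistics and skip dropout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "Conv1D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "Flatten",
    "Dropout",
    "Sequential",
    "Adam",
    "sigmoid",
    "weighted_bce_from_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_from_logits(
    z: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy and its gradient wrt the logits.

    Uses the softplus form ``w * (softplus(z) - y z)`` which is stable for
    large |z|; the gradient is ``w (sigma(z) - y) / n``.
    """
    z = z.ravel()
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(w * (softplus - y * z)))
    grad = (w * (sigmoid(z) - y) / z.size).reshape(-1, 1)
    return loss, grad


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv1D(Layer):
    """1-D convolution with 'same' zero padding, stride 1.

    Input ``(N, T, C_in)`` -> output ``(N, T, C_out)``. Weight layout is
    ``(kernel, C_in, C_out)``, applied by im2col + matmul.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        self.kernel = kernel
        self.c_in = c_in
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, t, c = x.shape
        p = self.kernel // 2
        xpad = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # (N, T, k, C): window j of position t is xpad[:, t+j, :]
        cols = np.lib.stride_tricks.sliding_window_view(xpad, self.kernel, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))
        return cols.reshape(n * t, self.kernel * c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        if t < self.kernel:
            raise ValueError(
                f"input length {t} shorter than kernel {self.kernel}"
            )
        cols = self._im2col(x)
        y = cols @ self.W.value + self.b.value
        if training:
            self._cols, self._shape = cols, x.shape
        return y.reshape(n, t, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, c_out = dy.shape
        dy_flat = dy.reshape(n * t, c_out)
        self.W.grad += self._cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.value.T).reshape(n, t, self.kernel, self.c_in)
        p = self.kernel // 2
        dxpad = np.zeros((n, t + 2 * p, self.c_in))
        for j in range(self.kernel):
            dxpad[:, j : j + t, :] += dcols[:, :, j, :]
        return dxpad[:, p : p + t, :]


class BatchNorm(Layer):
    """Batch normalisation over batch (and time, for 3-D inputs).

    Keeps exponential running statistics for inference; learnable scale and
    shift per channel.
    """

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if training:
            self._cache = (xhat, istd, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, istd, axes = self._cache
        m = np.prod([dy.shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * istd
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; an odd trailing sample is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t, c = x.shape
        t2 = t // self.pool
        blocks = x[:, : t2 * self.pool, :].reshape(n, t2, self.pool, c)
        arg = blocks.argmax(axis=2)
        if training:
            self._arg, self._t = arg, t
        return np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t2, c = dy.shape
        dblocks = np.zeros((n, t2, self.pool, c))
        np.put_along_axis(dblocks, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, self._t, c))
        dx[:, : t2 * self.pool, :] = dblocks.reshape(n, t2 * self.pool, c)
        return dx


class GlobalAvgPool1D(Layer):
    """Temporal average; the layer that buys input-length invariance."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._t, axis=1) / self._t


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dy
        return dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def parameter_count(layer: Layer) -> int:
    return int(sum(p.value.size for p in layer.params()))
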