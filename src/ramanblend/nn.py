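"""Minimal feed-forward / 1-D convolutional neural-network core.

Plain-numpy layers with hand-written backpropagation, sized for the small
spectral models this package trains (two conv blocks or two dense hidden
layers, a few million parameters).  Everything is seeded through
``numpy.random.Generator`` objects, so training is bit-reproducible.

Conventions: dense activations are ``(batch, features)``; convolutional
activations are ``(batch, channels, length)``.  Convolution is "valid"
(no padding), pooling is non-overlapping max pooling that discards any
trailing remainder.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid

__all__ = [
    "sigmoid",
    "softplus",
    "bce_with_logits",
    "truncated_normal",
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "ReLU",
    "ELU",
    "Flatten",
    "Sequential",
    "Adam",
]


def softplus(z):
    return np.logaddexp(0.0, z)


def bce_with_logits(z, y):
    """Elementwise binary cross-entropy of logits ``z`` against targets ``y``."""
    return softplus(z) - y * z


def truncated_normal(shape, sd: float, rng: np.random.Generator, trunc: float = 2.0):
    """Normal(0, sd) draws resampled until within ``trunc`` standard deviations."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > trunc * sd
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > trunc * sd
    return out


class Layer:
    def forward(self, x, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError

    def params(self):
        return []

    def grads(self):
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 weight_sd: float = 0.1, bias_init: float = 0.1):
        self.W = truncated_normal((n_in, n_out), weight_sd, rng)
        self.b = np.full(n_out, bias_init)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class Conv1D(Layer):
    """Valid 1-D convolution with kernel shape (filters, channels, length)."""

    def __init__(self, n_in: int, n_filters: int, kernel: int,
                 rng: np.random.Generator, weight_sd: float = 0.1,
                 bias_init: float = 0.1):
        self.kernel = kernel
        self.W = truncated_normal((n_filters, n_in, kernel), weight_sd, rng)
        self.b = np.full(n_filters, bias_init)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"input length {x.shape[2]} shorter than kernel {self.kernel}"
            )
        self._win = sliding_window_view(x, self.kernel, axis=2)  # (N,C,Lout,K)
        return np.einsum("nclk,fck->nfl", self._win, self.W) + self.b[None, :, None]

    def backward(self, g):
        self.gW = np.einsum("nclk,nfl->fck", self._win, g)
        self.gb = g.sum(axis=(0, 2))
        k = self.kernel
        gpad = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = sliding_window_view(gpad, k, axis=2)  # (N,F,L,K)
        return np.einsum("nflk,fck->ncl", gwin, self.W[:, :, ::-1])

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        p = self.pool
        n, c, length = x.shape
        lout = length // p
        if lout < 1:
            raise ValueError(f"input length {length} shorter than pool {p}")
        self._in_shape = x.shape
        xt = x[:, :, : lout * p].reshape(n, c, lout, p)
        self._argmax = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, g):
        n, c, length = self._in_shape
        p = self.pool
        lout = length // p
        gx = np.zeros((n, c, lout, p))
        np.put_along_axis(gx, self._argmax[..., None], g[..., None], axis=3)
        out = np.zeros(self._in_shape)
        out[:, :, : lout * p] = gx.reshape(n, c, lout * p)
        return out


class Dropout(Layer):
    def __init__(self, rate: float):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, g):
        return g * self._pos


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._out = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._pos = x > 0
        return self._out

    def backward(self, g):
        return g * np.where(self._pos, 1.0, self._out + self.alpha)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
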