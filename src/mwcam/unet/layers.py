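"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the spectrum-translation U-NET needs: valid convolutions with
zero padding (im2col), batch normalization, ReLU, and a dense linear layer.
Each layer exposes ``forward(x, training)`` and ``backward(grad)``; learnable
parameters and their gradients are reachable through ``params()``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Param:
    """A tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _im2col(x: np.ndarray, k: int, pad: int):
    """(N, C, H, W) -> columns (N, C*k*k, L) for a valid conv after padding."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - k + 1, wp - k + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, k, k, oh, ow), strides=(s0, s1, s2, s3, s2, s3)
    )
    return view.reshape(n, c * k * k, oh * ow), (oh, ow), x.shape


def _col2im(cols: np.ndarray, padded_shape, k: int, pad: int, out_hw):
    """Adjoint of :func:`_im2col`: scatter columns back onto the padded image."""
    n, c, hp, wp = padded_shape
    oh, ow = out_hw
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            x[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


class Conv2d(Layer):
    """Stride-1 convolution, output size = in - k + 1 + 2*pad."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        pad: int,
        rng: np.random.Generator,
        dtype=np.float64,
    ):
        self.c_in, self.c_out, self.k, self.pad = c_in, c_out, k, pad
        fan_in = c_in * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.w = Param(rng.uniform(-bound, bound, size=(c_out, c_in, k, k)).astype(dtype))
        self.b = Param(rng.uniform(-bound, bound, size=(c_out,)).astype(dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        cols, out_hw, padded_shape = _im2col(x, self.k, self.pad)
        self._cache = (cols, out_hw, padded_shape, x.shape[0])
        wmat = self.w.value.reshape(self.c_out, -1)
        out = np.einsum("of,nfl->nol", wmat, cols, optimize=True)
        out += self.b.value[None, :, None]
        n = x.shape[0]
        return out.reshape(n, self.c_out, *out_hw)

    def backward(self, grad):
        cols, out_hw, padded_shape, n = self._cache
        g = grad.reshape(n, self.c_out, -1)
        self.w.grad += np.einsum("nol,nfl->of", g, cols, optimize=True).reshape(
            self.w.value.shape
        )
        self.b.grad += g.sum(axis=(0, 2))
        wmat = self.w.value.reshape(self.c_out, -1)
        dcols = np.einsum("of,nol->nfl", wmat, g, optimize=True)
        return _col2im(dcols, padded_shape, self.k, self.pad, out_hw)


class BatchNorm2d(Layer):
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gx = grad * self.gamma.value[None, :, None, None]
        if not training:
            return gx * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        term = gx - gx.mean(axis=(0, 2, 3), keepdims=True) - xhat * (
            (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float64):
        bound = 1.0 / np.sqrt(n_in)
        self.w = Param(rng.uniform(-bound, bound, size=(n_out, n_in)).astype(dtype))
        self.b = Param(rng.uniform(-bound, bound, size=(n_out,)).astype(dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            g = g * g
            g *= 1.0 - b2
            v += g
            denom = np.sqrt(v / bc2)
            denom += self.eps
            np.divide(m, denom, out=denom)
            denom *= self.lr / bc1
            p.value -= denom
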