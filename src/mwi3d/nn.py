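"""Minimal dense NumPy layers with hand-written backpropagation.

Supports the small convolutional encoder-decoder networks this package
trains: N-dimensional same-padding convolutions (kernel-offset loops, so
memory stays linear in the volume), 2x max-pooling, 2x stride-2
transposed convolutions, ReLU, Glorot-uniform initialization and Adam.
Spatial dimensionality (2-D or 3-D) is inferred from the input.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = ["Conv", "UpConv", "MaxPool", "ReLU", "Adam", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self):
        """List of (name, value, gradient) triples."""
        return []

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0


class Conv(Layer):
    """Same-padding stride-1 convolution over 2 or 3 spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, ndim: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch, self.kernel, self.ndim = in_ch, out_ch, kernel, ndim
        kvol = kernel ** ndim
        self.w = glorot_uniform(rng, (out_ch, in_ch) + (kernel,) * ndim,
                                in_ch * kvol, out_ch * kvol)
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._offsets = list(product(range(kernel), repeat=ndim))

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def _pad(self, x):
        p = self.kernel // 2
        return np.pad(x, [(0, 0), (0, 0)] + [(p, p)] * self.ndim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        spatial = x.shape[2:]
        xp = self._pad(x)
        self._xp = xp
        y = np.zeros((x.shape[0], self.out_ch) + spatial, dtype=x.dtype)
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            y += np.einsum("oc,bc...->bo...",
                           self.w[(slice(None), slice(None)) + off], xp[sl])
        y += self.b.reshape((1, -1) + (1,) * self.ndim)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        spatial = gy.shape[2:]
        gxp = np.zeros_like(self._xp)
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            widx = (slice(None), slice(None)) + off
            ax = (0,) + tuple(range(2, gy.ndim))
            self.gw[widx] += np.tensordot(gy, self._xp[sl], axes=(ax, ax))
            gxp[sl] += np.einsum("oc,bo...->bc...", self.w[widx], gy)
        self.gb += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        p = self.kernel // 2
        sl = (slice(None), slice(None)) + tuple(
            slice(p, p + s) for s in spatial)
        self._xp = None
        return gxp[sl]


class UpConv(Layer):
    """Transposed convolution, kernel 2, stride 2 (non-overlapping)."""

    def __init__(self, in_ch: int, out_ch: int, ndim: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch, self.ndim = in_ch, out_ch, ndim
        kvol = 2 ** ndim
        self.w = glorot_uniform(rng, (in_ch, out_ch) + (2,) * ndim,
                                in_ch, out_ch * kvol)
        self.b = np.zeros(out_ch)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._offsets = list(product(range(2), repeat=ndim))

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = tuple(2 * s for s in x.shape[2:])
        y = np.empty((x.shape[0], self.out_ch) + spatial, dtype=x.dtype)
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, None, 2) for o in off)
            widx = (slice(None), slice(None)) + off
            y[sl] = np.einsum("co,bc...->bo...", self.w[widx], x)
        y += self.b.reshape((1, -1) + (1,) * self.ndim)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.zeros_like(self._x)
        for off in self._offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(o, None, 2) for o in off)
            widx = (slice(None), slice(None)) + off
            ax = (0,) + tuple(range(2, gy.ndim))
            self.gw[widx] += np.tensordot(gy[sl], self._x, axes=(ax, ax)).T
            gx += np.einsum("co,bo...->bc...", self.w[widx], gy[sl])
        self.gb += gy.sum(axis=(0,) + tuple(range(2, gy.ndim)))
        self._x = None
        return gx


class MaxPool(Layer):
    """Factor-2 max pooling; gradient split evenly among tied maxima."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def _blocks(self, x):
        shape = [x.shape[0], x.shape[1]]
        for s in x.shape[2:]:
            if s % 2:
                raise ValueError("max-pool input extents must be even")
            shape += [s // 2, 2]
        xb = x.reshape(shape)
        axes = tuple(3 + 2 * d for d in range(self.ndim))
        return xb, axes

    def forward(self, x: np.ndarray) -> np.ndarray:
        xb, axes = self._blocks(x)
        m = xb.max(axis=axes, keepdims=True)
        self._mask = (xb == m)
        self._cnt = self._mask.sum(axis=axes, keepdims=True)
        self._in_shape = x.shape
        out = m
        for ax in sorted(axes, reverse=True):
            out = np.squeeze(out, axis=ax)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        shape = list(gy.shape[:2])
        for s in gy.shape[2:]:
            shape += [s, 1]
        g = gy.reshape(shape)
        gxb = self._mask * (g / self._cnt)
        out = gxb.reshape(self._in_shape)
        self._mask = self._cnt = None
        return out


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        out = gy * self._mask
        self._mask = None
        return out


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params()]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}
        for li, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                self.state[(li, name)] = (np.zeros_like(value),
                                          np.zeros_like(value))

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, value, grad in layer.params():
                m, v = self.state[(li, name)]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad ** 2
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
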