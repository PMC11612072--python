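"""Minimal CPU neural-network layers with explicit backpropagation.

Everything operates on NCHW float32 arrays.  Layers are functional: ``forward``
returns ``(output, cache)`` and ``backward`` consumes that cache, so one layer
object can appear several times in a single computation (this is what makes
weight-shared siamese branches trivial — both branches literally are the same
layer objects, and their gradients accumulate in the shared parameters).

Convolution is im2col + matmul; the backward pass recomputes the column view
from the cached padded input, keeping per-layer memory at one activation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "Upsample2x",
    "GlobalAvgPool",
    "Linear",
    "Sigmoid",
    "ChannelSoftmax",
    "Sequential",
    "ResBlock",
]

DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, gy, cache):  # -> gx
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution with 'same' padding (stride 1) or stride-2 downsampling.

    He-normal initialization; ``w_scale`` shrinks it (used for the last conv of
    a residual block so blocks start close to identity).
    """

    def __init__(self, cin: int, cout: int, ksize: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, w_scale: float = 1.0):
        rng = rng or np.random.default_rng()
        fan_in = cin * ksize * ksize
        std = w_scale * np.sqrt(2.0 / fan_in)
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, ksize, ksize)))
        self.b = Param(np.zeros(cout))
        self.ksize = ksize
        self.stride = stride
        self.pad = ksize // 2

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _cols(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        k, s = self.ksize, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c = xp.shape[0], xp.shape[1]
        # (N, C, OH, OW, k, k) -> (N*OH*OW, C*k*k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * k * k)

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        p, k, s = self.pad, self.ksize, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = self._cols(xp, oh, ow)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value
        y = y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        return y, (xp, (n, c, h, w), (oh, ow))

    def backward(self, gy, cache):
        xp, (n, c, h, w), (oh, ow) = cache
        k, s, p = self.ksize, self.stride, self.pad
        cout = gy.shape[1]
        gy_flat = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(n * oh * ow, cout)
        cols = self._cols(xp, oh, ow)
        self.W.grad += (gy_flat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += gy_flat.sum(axis=0)
        gcols = (gy_flat @ self.W.value.reshape(cout, -1)).reshape(n, oh, ow, c, k, k)
        gxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                gxp[:, :, ki:ki + s * (oh - 1) + 1:s, kj:kj + s * (ow - 1) + 1:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, gy, cache):
        return gy * cache


class Upsample2x(Layer):
    """Nearest-neighbor 2x upsampling, optionally cropped to a target size."""

    def forward(self, x, out_hw: tuple[int, int] | None = None):
        y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        full_hw = y.shape[2:]
        if out_hw is not None:
            y = y[:, :, : out_hw[0], : out_hw[1]]
        return y, (x.shape, full_hw)

    def backward(self, gy, cache):
        x_shape, full_hw = cache
        if gy.shape[2:] != full_hw:
            pad_h = full_hw[0] - gy.shape[2]
            pad_w = full_hw[1] - gy.shape[3]
            gy = np.pad(gy, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
        n, c, h2, w2 = gy.shape
        return gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, gy, cache):
        n, c, h, w = cache
        return np.broadcast_to(gy[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = Param(rng.normal(0.0, np.sqrt(1.0 / din), size=(dout, din)))
        self.b = Param(np.zeros(dout))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x):
        return x @ self.W.value.T + self.b.value, x

    def backward(self, gy, cache):
        self.W.grad += gy.T @ cache
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return y, y

    def backward(self, gy, cache):
        return gy * cache * (1.0 - cache)


class ChannelSoftmax(Layer):
    """Per-pixel softmax over the channel axis."""

    def forward(self, x):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        return p, p

    def backward(self, gy, cache):
        p = cache
        dot = (gy * p).sum(axis=1, keepdims=True)
        return p * (gy - dot)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, gy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(gy, c)
        return gy


class ResBlock(Layer):
    """conv-relu-conv with an identity skip, relu after the sum."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.conv2 = Conv2d(channels, channels, rng=rng, w_scale=0.1)
        self.relu1 = ReLU()
        self.relu2 = ReLU()

    def params(self) -> list[Param]:
        return self.conv1.params() + self.conv2.params()

    def forward(self, x):
        h, c1 = self.conv1.forward(x)
        a, ca = self.relu1.forward(h)
        h2, c2 = self.conv2.forward(a)
        y, co = self.relu2.forward(x + h2)
        return y, (c1, ca, c2, co)

    def backward(self, gy, cache):
        c1, ca, c2, co = cache
        g = self.relu2.backward(gy, co)
        g2 = self.conv2.backward(g, c2)
        g1 = self.relu1.backward(g2, ca)
        return self.conv1.backward(g1, c1) + g
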