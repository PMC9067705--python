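"""Minimal CNN layer framework on numpy, with explicit backprop.

Provides exactly what the counting networks need: 2-D convolution (im2col),
ReLU, max pooling, frozen-statistics batch normalization, residual
bottleneck blocks, a sequential container and an Adam optimizer. Each
layer's ``forward`` returns ``(output, cache)`` and ``backward`` consumes
``(grad_output, cache)``, so several forward passes (e.g. the labelled
branch plus both Siamese ranking branches, all sharing parameters) can be
taken before a single backward sweep accumulates gradients.

Arrays are ``(N, C, H, W)`` float64 throughout; float64 keeps the finite-
difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "BatchNorm2d",
    "Sequential",
    "Bottleneck",
    "Adam",
    "xavier_uniform",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = view.transpose(0, 4, 5, 1, 2, 3).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(dcols, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dxp = np.zeros((n, c, hp, wp))
    d6 = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        self.weight = Param(
            xavier_uniform((out_channels, in_channels, k, k), fan_in, fan_out, rng),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias") if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        n = x.shape[0]
        k = self.kernel_size
        cols, (oh, ow) = _im2col(x, k, k, self.stride, self.padding)
        w2 = self.weight.value.reshape(self.out_channels, -1)
        y = cols @ w2.T
        if self.bias is not None:
            y += self.bias.value
        y = y.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)
        return y, (x.shape, cols, oh, ow)

    def backward(self, dy, cache):
        x_shape, cols, oh, ow = cache
        n = x_shape[0]
        k = self.kernel_size
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        self.weight.grad += (dy2.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        dcols = dy2 @ self.weight.value.reshape(self.out_channels, -1)
        return _col2im(dcols, x_shape, k, k, self.stride, self.padding, oh, ow)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class MaxPool2d(Layer):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.kernel_size
        xr = x.reshape(n * c, 1, h, w)
        if self.padding:
            xr = np.pad(
                xr,
                ((0, 0), (0, 0), (self.padding,) * 2, (self.padding,) * 2),
                constant_values=-np.inf,
            )
            pad = 0
        else:
            pad = 0
        cols, (oh, ow) = _im2col(xr, k, k, self.stride, pad)
        arg = cols.argmax(axis=1)
        y = cols[np.arange(cols.shape[0]), arg]
        y = y.reshape(n, c, oh, ow)
        return y, (x.shape, xr.shape, arg, oh, ow)

    def backward(self, dy, cache):
        x_shape, xr_shape, arg, oh, ow = cache
        n, c, h, w = x_shape
        k = self.kernel_size
        dcols = np.zeros((n * c * oh * ow, k * k))
        dcols[np.arange(dcols.shape[0]), arg] = dy.reshape(-1)
        dxr = _col2im(dcols, xr_shape, k, k, self.stride, 0, oh, ow)
        p = self.padding
        dxr = dxr[:, :, p : p + h, p : p + w] if p else dxr
        return dxr.reshape(n, c, h, w)


class BatchNorm2d(Layer):
    """Normalization by frozen running statistics (fine-tuning-style BN).

    ``y = gamma * (x - mean) / sqrt(var + eps) + beta`` with fixed
    per-channel mean/var, which keeps the forward pass deterministic for
    any batch size and makes the backward pass a per-channel scaling.
    """

    def __init__(self, channels: int, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[:, None, None]) * inv[:, None, None]
        y = xhat * self.gamma.value[:, None, None] + self.beta.value[:, None, None]
        return y, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        return dy * (self.gamma.value * inv)[:, None, None]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 reduce, 3x3, 1x1 expand, with identity skip."""

    expansion = 4

    def __init__(
        self,
        in_channels: int,
        width: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "block",
    ):
        out_channels = width * self.expansion
        self.main = Sequential(
            Conv2d(in_channels, width, 1, bias=False, rng=rng, name=f"{name}.conv1"),
            BatchNorm2d(width, name=f"{name}.bn1"),
            ReLU(),
            Conv2d(width, width, 3, stride=stride, padding=1, bias=False, rng=rng, name=f"{name}.conv2"),
            BatchNorm2d(width, name=f"{name}.bn2"),
            ReLU(),
            Conv2d(width, out_channels, 1, bias=False, rng=rng, name=f"{name}.conv3"),
            BatchNorm2d(out_channels, name=f"{name}.bn3"),
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, bias=False, rng=rng, name=f"{name}.down"),
                BatchNorm2d(out_channels, name=f"{name}.downbn"),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    def params(self):
        out = self.main.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x):
        y, main_cache = self.main.forward(x)
        if self.shortcut is not None:
            skip, short_cache = self.shortcut.forward(x)
        else:
            skip, short_cache = x, None
        out, relu_cache = self.relu.forward(y + skip)
        return out, (main_cache, short_cache, relu_cache)

    def backward(self, dy, cache):
        main_cache, short_cache, relu_cache = cache
        dsum = self.relu.backward(dy, relu_cache)
        dx = self.main.backward(dsum, main_cache)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dsum, short_cache)
        else:
            dx = dx + dsum
        return dx


class Adam:
    """Adam over a flat parameter list (framework-default betas/eps)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
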