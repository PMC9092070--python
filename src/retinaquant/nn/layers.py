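"""NumPy layers with explicit forward/backward passes.

All layers operate on NCHW float64 arrays.  Each layer caches what its
backward pass needs on ``self``; ``backward`` consumes the upstream
gradient and accumulates parameter gradients into ``Param.grad``.
Convolutions use same padding (shape-preserving), implemented as one
GEMM per kernel offset so the hot loop stays inside BLAS.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "ConvTranspose2d",
    "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k×k same-padding convolution (k odd, stride 1)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: Optional[np.random.Generator] = None, name: str = "conv"):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(c_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp, self._hw = xp, (h, w)
        out = np.broadcast_to(
            self.bias.data[None, :, None, None], (n, self.c_out, h, w)).copy()
        out2 = out.reshape(n, self.c_out, h * w)
        wmat = self.weight.data
        for dy in range(self.k):
            for dx in range(self.k):
                xs = np.ascontiguousarray(
                    xp[:, :, dy:dy + h, dx:dx + w]).reshape(n, c, h * w)
                out2 += np.matmul(wmat[:, :, dy, dx], xs)
        return out

    def backward(self, dout):
        n = dout.shape[0]
        h, w = self._hw
        p = self.k // 2
        xp = self._xp
        dflat = dout.reshape(n, self.c_out, h * w)
        dxp = np.zeros_like(xp)
        for dy in range(self.k):
            for dx in range(self.k):
                xs = np.ascontiguousarray(
                    xp[:, :, dy:dy + h, dx:dx + w]).reshape(n, self.c_in, h * w)
                self.weight.grad[:, :, dy, dx] += np.einsum(
                    "nop,ncp->oc", dflat, xs, optimize=True)
                dxs = np.matmul(self.weight.data[:, :, dy, dx].T, dflat)
                dxp[:, :, dy:dy + h, dx:dx + w] += dxs.reshape(n, self.c_in, h, w)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self._xp = None
        if p == 0:
            return dxp
        return dxp[:, :, p:p + h, p:p + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * istd[None, :, None, None]
        if train:
            self._cache = (xhat, istd, x.shape)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None])

    def backward(self, dy):
        xhat, istd, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (istd[None, :, None, None] / m) * (
            m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = (dxr.reshape(n, c, h // 2, w // 2, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(n, c, h, w))
        self._idx = None
        return dx


class ConvTranspose2d(Layer):
    """2×2 stride-2 transposed convolution (exact twofold upsampling)."""

    def __init__(self, c_in: int, c_out: int,
                 rng: Optional[np.random.Generator] = None, name: str = "upconv"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(c_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x = x
        xflat = x.reshape(n, c, h * w)
        out = np.empty((n, self.c_out, 2 * h, 2 * w))
        for dy in range(2):
            for dx in range(2):
                o = np.matmul(self.weight.data[:, :, dy, dx].T, xflat)
                out[:, :, dy::2, dx::2] = o.reshape(n, self.c_out, h, w)
        out += self.bias.data[None, :, None, None]
        return out

    def backward(self, dout):
        x = self._x
        n, c, h, w = x.shape
        xflat = x.reshape(n, c, h * w)
        dx = np.zeros_like(xflat)
        for dy in range(2):
            for dx_ in range(2):
                ds = np.ascontiguousarray(
                    dout[:, :, dy::2, dx_::2]).reshape(n, self.c_out, h * w)
                self.weight.grad[:, :, dy, dx_] += np.einsum(
                    "ncp,nop->co", xflat, ds, optimize=True)
                dx += np.matmul(self.weight.data[:, :, dy, dx_], ds)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        self._x = None
        return dx.reshape(n, c, h, w)


class Adam:
    """Adam over a parameter list; the learning rate is supplied per step
    so an external schedule stays in control."""

    def __init__(self, params: List[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
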