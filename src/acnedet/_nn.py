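"""Minimal CPU neural-network layers with hand-written gradients.

Everything runs on numpy in NCHW layout, float64.  Each layer caches what
its backward pass needs during forward; ``backward(dy)`` accumulates
parameter gradients and returns the gradient w.r.t. its input.  This keeps
the dependency surface tiny and makes the desk-scale models fully
deterministic given a seed.

Convolution is computed as a sum of shifted-slice tensor contractions (one
per kernel offset), which is fast enough for the small feature maps used
here without an im2col buffer.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base: layers expose parameters() and a forward/backward pair."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True) -> None:
        self.training = mode

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._xp: np.ndarray | None = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, _, h, w = x.shape
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp, self._in_hw = xp, (h, w)
        acc = np.zeros((n, ho, wo, self.weight.data.shape[0]), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                sl = xp[:, :, di : di + s * ho : s, dj : dj + s * wo : s]
                acc += np.tensordot(sl, self.weight.data[:, :, di, dj], axes=([1], [1]))
        out = np.moveaxis(acc, 3, 1)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = self._xp
        n, _, hp, wp = xp.shape
        ho, wo = dy.shape[2], dy.shape[3]
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                sl = xp[:, :, di : di + s * ho : s, dj : dj + s * wo : s]
                # (Cout, Cin) contribution for this offset
                self.weight.grad[:, :, di, dj] += np.tensordot(
                    dy, sl, axes=([0, 2, 3], [0, 2, 3])
                )
                contrib = np.tensordot(dy, self.weight.data[:, :, di, dj], axes=([1], [0]))
                dxp[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += np.moveaxis(
                    contrib, 3, 1
                )
        h, w = self._in_hw
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_f), (out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f))
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class SiLU(Layer):
    """x * sigmoid(x), the activation used in modern detector backbones."""

    def forward(self, x):
        s = 1.0 / (1.0 + np.exp(-x))
        self._x, self._s = x, s
        return x * s

    def backward(self, dy):
        s = self._s
        return dy * (s + self._x * s * (1.0 - s))


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._xhat, self._invstd = xhat, invstd
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, invstd, m = self._xhat, self._invstd, self._m
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not self.training:
            return dy * g * invstd[None, :, None, None]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class MaxPool2d(Layer):
    """Non-overlapping k x k max pooling; input H, W must be divisible by k."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x):
        k = self.k
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool size {k}")
        xr = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // k, w // k, k * k)
        self._arg = xr.argmax(axis=4)
        self._shape = x.shape
        return xr.max(axis=4)

    def backward(self, dy):
        k = self.k
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // k, w // k, k * k), dtype=DTYPE)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=4)
        dxr = dxr.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for l in self.layers:
            l.train(mode)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD with decoupled-from-nothing classic L2 weight decay."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=DTYPE)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out
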