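"""Minimal convolutional-network layers with reverse-mode gradients.

Everything the MGNet classifier and the detector need, in numpy with
float32 arithmetic: strided 2-D convolution (im2col + BLAS matmul),
depthwise convolution, batch normalization, ReLU6, nearest-neighbour
x2 upsampling, global average pooling, linear heads, softmax /
sigmoid cross-entropy losses, an Adam optimizer and a
reduce-on-plateau learning-rate scheduler.

Layers are stateful modules: ``forward`` caches what ``backward``
needs, ``backward`` accumulates parameter gradients and returns the
gradient with respect to the input.  Composite blocks (bottlenecks,
ghost modules, the PANet neck) wire these primitives together by hand
-- there is no autograd graph, which keeps the arithmetic transparent
and fast enough for desk-scale training on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConstructionError

_DT = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class; subclasses define forward/backward and list params."""

    training: bool = True

    def params(self) -> list:
        out = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.set_training(flag)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def __call__(self, x):
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Module):
    """k x k convolution, zero padding k//2, optional bias, NCHW layout."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        self.weight = Param(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Param(np.zeros(cout)) if bias else None
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ConstructionError(f"expected {self.cin} channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, oh, ow, k, k) -> (n*oh*ow, c*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * oh * ow, c * k * k)
        wmat = self.weight.value.reshape(self.cout, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cols, self._xshape = cols, (n, c, h, w, oh, ow)
        return np.ascontiguousarray(
            out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w, oh, ow = self._xshape
        k, s, p = self.k, self.stride, self.pad
        g = gout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.weight.grad += (g.T @ self._cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        dcols = (g @ self.weight.value.reshape(self.cout, -1)
                 ).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DT)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class DepthwiseConv2d(Module):
    """k x k per-channel convolution (groups == channels)."""

    def __init__(self, channels: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        self.weight = Param(_he_init(rng, (channels, k, k), k * k))
        self._win = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.einsum("nchwij,cij->nchw", win, self.weight.value,
                        optimize=True).astype(_DT)
        self._win, self._xshape = win, (n, c, h, w, out.shape[2], out.shape[3])
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w, oh, ow = self._xshape
        k, s, p = self.k, self.stride, self.pad
        self.weight.grad += np.einsum("nchw,nchwij->cij", gout, self._win,
                                      optimize=True)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DT)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += \
                    gout * self.weight.value[:, ki, kj][None, :, None, None]
        self._win = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat.astype(_DT), inv_std.astype(_DT))
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(_DT)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        sum_g = gout.sum(axis=(0, 2, 3))
        sum_gx = (gout * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad += sum_gx
        self.beta.grad += sum_g
        g = self.gamma.value[None, :, None, None]
        if not self.training:
            return (gout * g * inv_std[None, :, None, None]).astype(_DT)
        return ((g * inv_std[None, :, None, None] / m)
                * (m * gout - sum_g[None, :, None, None]
                   - xhat * sum_gx[None, :, None, None])).astype(_DT)


class ReLU6(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout * self._mask
        self._mask = None
        return g


class Upsample2x(Module):
    """Nearest-neighbour doubling of spatial size."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(gout[:, :, None, None], self._shape)
                / (h * w)).astype(_DT)


class Linear(Module):
    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (cout, cin), cin))
        self.bias = Param(np.zeros(cout)) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out.astype(_DT)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.weight.grad += gout.T @ self._x
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=0)
        g = gout @ self.weight.value
        self._x = None
        return g.astype(_DT)


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, gout):
        for m in reversed(self.modules):
            gout = m.backward(gout)
        return gout


def conv_bn_relu(cin: int, cout: int, k: int, stride: int,
                 rng: np.random.Generator) -> Sequential:
    return Sequential(Conv2d(cin, cout, k, stride, rng=rng),
                      BatchNorm2d(cout), ReLU6())


# ---------------------------------------------------------------------------
# Losses


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64), axis=1)
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-12))
    d = p.copy()
    d[np.arange(n), targets] -= 1.0
    return float(loss), (d / n).astype(_DT)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray,
                    weight: float = 1.0):
    """Element-mean binary cross-entropy; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    d = (sigmoid(z) - t) / z.size
    return float(weight * loss), (weight * d).astype(_DT)


# ---------------------------------------------------------------------------
# Optimization


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience``
    consecutive epochs without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.5,
                 patience: int = 3, min_delta: float = 0.0):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    @property
    def lr(self) -> float:
        return self.opt.lr

    def step(self, loss: float) -> bool:
        """Feed one epoch's monitored loss; True if the rate was cut."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.opt.lr *= self.factor
            self.stale = 0
            return True
        return False
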