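"""Minimal convolutional-network engine on numpy.

Implements exactly the pieces the four super-resolution architectures
need: same-padding stride-1 2-D convolution (im2col + BLAS matmul with
an explicit col2im backward), ReLU/PReLU, batch normalization, skip
connections with optional residual scaling, L1/MSE losses, Adam and
global-norm gradient clipping. Everything is float64 and fully
deterministic given a seeded ``numpy.random.Generator``; gradients are
exact (they are checked against finite differences in the test suite).

Layout is NCHW. Modules cache what their backward pass needs during
``forward``; a backward call therefore has to follow the forward call
whose gradient it propagates.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ReLU",
    "PReLU",
    "BatchNorm2d",
    "Sequential",
    "SkipConnection",
    "ResidualBlock",
    "mse_loss",
    "l1_loss",
    "Adam",
    "clip_global_norm",
]


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def modules(self):
        """Depth-first iteration over this module and all children."""
        yield self

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Conv2d(Module):
    """Stride-1 convolution with zero same-padding.

    He-normal initialisation; ``weight_scale`` shrinks the initial
    weights (used to start residual branches near zero so residual
    networks begin close to the identity map).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        weight_scale: float = 1.0,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        std = weight_scale * np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(out_channels, fan_in)))
        self.bias = Param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.kernel_size, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h * w, c * k * k
        )
        self._cols = cols if training else None
        self._in_shape = (n, c, h, w)
        y = cols @ self.weight.value.T + self.bias.value
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(
            n, self.out_channels, h, w
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward without a training-mode forward")
        n, c, h, w = self._in_shape
        k, p = self.kernel_size, self.pad
        gmat = grad.reshape(n, self.out_channels, h * w)
        # weight/bias gradients, summed over the batch
        self.weight.grad += np.matmul(gmat, self._cols).sum(axis=0)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        # input gradient: scatter the column gradient back (col2im)
        gcols = (gmat.transpose(0, 2, 1) @ self.weight.value).reshape(
            n, h, w, c, k, k
        )
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di : di + h, dj : dj + w] += gcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        self._cols = None
        return gxp[:, :, p : p + h, p : p + w]

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class PReLU(Module):
    """Per-channel parametric rectifier, slope initialised at 0.25."""

    def __init__(self, channels: int, init: float = 0.25) -> None:
        self.alpha = Param(np.full(channels, init))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        a = self.alpha.value[None, :, None, None]
        return np.where(x > 0, x, a * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        neg = x <= 0
        self.alpha.grad += (grad * x * neg).sum(axis=(0, 2, 3))
        a = self.alpha.value[None, :, None, None]
        return grad * np.where(neg, a, 1.0)

    def params(self) -> list[Param]:
        return [self.alpha]


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if training:
            self._xhat, self._ivar = xhat, ivar
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return ivar[None, :, None, None] * (g - gsum / m - xhat * gxsum / m)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def modules(self):
        yield self
        for layer in self.layers:
            yield from layer.modules()


class SkipConnection(Module):
    """``y = x + scale * body(x)`` — identity when the body outputs 0."""

    def __init__(self, body: Module, scale: float = 1.0) -> None:
        self.body = body
        self.scale = scale

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x + self.scale * self.body.forward(x, training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.scale * self.body.backward(grad)

    def params(self) -> list[Param]:
        return self.body.params()

    def modules(self):
        yield self
        yield from self.body.modules()


class ResidualBlock(SkipConnection):
    """Marker subclass for the repeated in-trunk residual blocks."""


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


class Adam:
    """Adaptive-moment optimiser (Kingma & Ba defaults)."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_global_norm(params: list[Param], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params))
    if total > max_norm and total > 0:
        factor = max_norm / total
        for p in params:
            p.grad *= factor
    return total
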