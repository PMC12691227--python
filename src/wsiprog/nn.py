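"""Compact feed-forward neural-network engine (NumPy, manual backpropagation).

Implements exactly the layer set the risk models need — 2-D convolution
(optionally grouped), batch normalization, ReLU, global average pooling,
fully connected layers, residual blocks — plus an Adam optimizer with L2
weight decay. Everything runs in float64 on the CPU with explicitly seeded
initialization, so training is bit-reproducible across runs.

Conventions
-----------
* Image tensors are ``(N, C, H, W)``; feature tensors are ``(N, F)``.
* ``forward(x, train=...)`` caches whatever ``backward`` needs; ``backward``
  accumulates parameter gradients and returns the gradient w.r.t. its input.
* ``zero_grad`` must be called between optimization steps.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Linear", "ReLU", "Flatten", "GlobalAvgPool",
    "Conv2d", "BatchNorm2d", "BatchNorm1d", "Residual", "Sequential", "Adam",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g):
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Conv2d(Layer):
    """2-D convolution via im2col; supports stride, zero padding, and groups."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1):
        if c_in % groups or c_out % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (c_in // groups) * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        # weight layout: (groups, c_out/g, c_in/g * k * k)
        self.w = Param(rng.normal(0.0, scale,
                                  size=(groups, c_out // groups, fan_in)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        # xp: (N, C, Hp, Wp) -> (N, ho, wo, C, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]          # (N, C, ho, wo, k, k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p, s, k = self.padding, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo)                        # (N, ho, wo, C, k, k)
        g, cg = self.groups, self.c_in // self.groups
        cols = cols.reshape(n, ho, wo, g, cg * k * k)
        self._cols, self._xshape, self._ho, self._wo = cols, x.shape, ho, wo
        # einsum over groups: (N,ho,wo,g,f) x (g,og,f) -> (N,ho,wo,g,og)
        out = np.einsum("nhwgf,gof->nhwgo", cols, self.w.value, optimize=True)
        out = out.reshape(n, ho, wo, self.c_out) + self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad_out):
        n, _, h, w = self._xshape
        p, s, k = self.padding, self.stride, self.k
        ho, wo = self._ho, self._wo
        g, cg = self.groups, self.c_in // self.groups
        go = grad_out.transpose(0, 2, 3, 1).reshape(n, ho, wo, g, self.c_out // g)
        self.b.grad += grad_out.sum(axis=(0, 2, 3))
        self.w.grad += np.einsum("nhwgo,nhwgf->gof", go, self._cols, optimize=True)
        gcols = np.einsum("nhwgo,gof->nhwgf", go, self.w.value, optimize=True)
        gcols = gcols.reshape(n, ho, wo, self.c_in, k, k)
        gxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p))
        for a in range(k):
            for b in range(k):
                gxp[:, :, a:a + ho * s:s, b:b + wo * s:s] += \
                    gcols[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class _BatchNormBase(Layer):
    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def params(self):
        return [self.gamma, self.beta]

    _axes: tuple  # reduction axes, set by subclass

    def _expand(self, v):
        raise NotImplementedError

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean)) * self._expand(inv)
        self._xhat, self._inv, self._train = xhat, inv, train
        return self._expand(self.gamma.value) * xhat + self._expand(self.beta.value)

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        axes = self._axes
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gx = g * self._expand(self.gamma.value)
        if not self._train:
            return gx * self._expand(inv)
        m = np.prod([xhat.shape[a] for a in axes])
        mean_g = gx.mean(axis=axes)
        mean_gx = (gx * xhat).mean(axis=axes)
        return self._expand(inv) * (gx - self._expand(mean_g)
                                    - xhat * self._expand(mean_gx))


class BatchNorm2d(_BatchNormBase):
    _axes = (0, 2, 3)

    def _expand(self, v):
        return v[None, :, None, None]


class BatchNorm1d(_BatchNormBase):
    _axes = (0,)

    def _expand(self, v):
        return v[None, :]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Residual(Layer):
    """body(x) + shortcut(x), ReLU after the sum."""

    def __init__(self, body: Sequential, shortcut: Sequential | None = None):
        self.body = body
        self.shortcut = shortcut
        self.relu = ReLU()

    def params(self):
        p = self.body.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, train=True):
        y = self.body.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.relu.forward(y + s, train=train)

    def backward(self, g):
        g = self.relu.backward(g)
        gs = g if self.shortcut is None else self.shortcut.backward(g)
        gb = self.body.backward(g)
        return gb + gs


def zero_grad(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        zero_grad(self.params)
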