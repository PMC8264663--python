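"""Minimal CPU neural-network layers with hand-written gradients.

A small, self-contained layer library (convolution, transposed convolution,
batch normalization, dropout, mean pooling, ReLU activations) sufficient to
express image-to-image regression networks, plus the ADAM optimizer. All
arithmetic is float64 numpy; convolutions are lowered to BLAS matrix
multiplies through an im2col transform. Every layer implements
``forward(x, training, rng)`` and ``backward(grad)``; gradients accumulate
into ``Parameter.grad`` and are validated against finite differences in the
test suite.

Randomness (initialization, dropout masks) is drawn exclusively from
explicitly passed ``numpy.random.Generator`` streams, so training runs are
reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Dropout",
    "LeakyReLU",
    "ReLU",
    "MeanPool2d",
    "Sequential",
    "Adam",
]


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


# -- convolution plumbing ---------------------------------------------------


def _windows(x_padded: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Sliding stencil view of shape (N, C, Ho, Wo, kh, kw)."""
    win = sliding_window_view(x_padded, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _col2im(
    dwin: np.ndarray, n: int, c: int, h: int, w: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of the window view: scatter-add stencil grads back to pixels."""
    _, _, ho, wo, kh, kw = dwin.shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dwin[:, :, :, :, i, j]
            )
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]
    return out


def _conv_forward(x, weight, bias, stride, pad):
    """y[n,o] = sum_c W[o,c] * x[n,c] windows; returns (y, flattened cols)."""
    n, c, h, w = x.shape
    o, _, kh, kw = weight.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = _windows(xp, kh, kw, stride)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    y = cols @ weight.reshape(o, -1).T
    if bias is not None:
        y += bias
    return y.reshape(n, ho, wo, o).transpose(0, 3, 1, 2), cols


def _conv_backward(dy, cols, weight, xshape, stride, pad):
    """Gradients of _conv_forward w.r.t. weight, bias and input."""
    n, c, h, w = xshape
    o, _, kh, kw = weight.shape
    dyr = dy.transpose(0, 2, 3, 1).reshape(-1, o)
    dw = (dyr.T @ cols).reshape(weight.shape)
    db = dy.sum(axis=(0, 2, 3))
    dcols = dyr @ weight.reshape(o, -1)
    ho, wo = dy.shape[2], dy.shape[3]
    dwin = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dx = _col2im(dwin, n, c, h, w, stride, pad)
    return dw, db, dx


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Layer):
    """3x3-style dense convolution, stride/padding configurable."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        )
        self.bias = Parameter(_kaiming_uniform(rng, (out_ch,), fan_in))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False, rng=None):
        y, cols = _conv_forward(
            x, self.weight.value, self.bias.value, self.stride, self.padding
        )
        self._cache = (cols, x.shape)
        return y

    def backward(self, grad):
        cols, xshape = self._cache
        dw, db, dx = _conv_backward(
            grad, cols, self.weight.value, xshape, self.stride, self.padding
        )
        self.weight.grad += dw
        self.bias.grad += db
        return dx


class ConvTranspose2d(Layer):
    """Transposed (fractionally strided) convolution.

    Output spatial size is ``(in - 1) * stride - 2 * padding + kernel``; the
    forward pass is the exact adjoint of the matching strided convolution.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_ch * kernel * kernel
        # stored in conv orientation: (in_ch, out_ch, k, k)
        self.weight = Parameter(
            _kaiming_uniform(rng, (in_ch, out_ch, kernel, kernel), fan_in)
        )
        self.bias = Parameter(_kaiming_uniform(rng, (out_ch,), fan_in))
        self._cache = None

    def parameters(self):
        return [self.weight, self.bias]

    def out_size(self, in_size: int) -> int:
        return (in_size - 1) * self.stride - 2 * self.padding + self.kernel

    def forward(self, x, training=False, rng=None):
        n, ci, hi, wi = x.shape
        _, co, kh, kw = self.weight.value.shape
        ho, wo = self.out_size(hi), self.out_size(wi)
        # scatter each input pixel's stencil into the larger output grid
        dwin = np.einsum(
            "nohw,ocij->nchwij", x, self.weight.value, optimize=True
        )  # o = in_ch (conv-output role), c = out_ch
        y = _col2im(dwin, n, co, ho, wo, self.stride, self.padding)
        y += self.bias.value[None, :, None, None]
        self._cache = (x, (n, co, ho, wo))
        return y

    def backward(self, grad):
        x, (n, co, ho, wo) = self._cache
        p, s, k = self.padding, self.stride, self.kernel
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p))) if p else grad
        win = _windows(gp, k, k, s)  # (N, out_ch, Hi, Wi, k, k)
        self.weight.grad += np.einsum("nchwij,nohw->ocij", win, x, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dx = np.einsum("nchwij,ocij->nohw", win, self.weight.value, optimize=True)
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable scale and shift.

    Training uses batch statistics over (N, H, W) and updates running
    estimates with the given momentum; inference normalizes with the frozen
    running statistics, making evaluation deterministic.
    """

    def __init__(self, ch, eps=1e-5, momentum=0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False, rng=None):
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
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not training:
            return g * inv[None, :, None, None]
        # batch statistics depend on x: full normalization gradient
        gm = g.mean(axis=(0, 2, 3), keepdims=True)
        gxm = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (g - gm - xhat * gxm)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng stream")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._pos = None

    def forward(self, x, training=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._pos, grad, self.slope * grad)


class ReLU(Layer):
    def __init__(self):
        self._pos = None

    def forward(self, x, training=False, rng=None):
        self._pos = x > 0
        return x * self._pos

    def backward(self, grad):
        return grad * self._pos


class MeanPool2d(Layer):
    """2x2 (or kxk) mean pooling, floor mode: odd remainders are dropped."""

    def __init__(self, kernel: int = 2):
        self.k = kernel
        self._shape = None

    def forward(self, x, training=False, rng=None):
        k = self.k
        n, c, h, w = x.shape
        ho, wo = h // k, w // k
        self._shape = x.shape
        xc = x[:, :, : ho * k, : wo * k]
        return xc.reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    def backward(self, grad):
        k = self.k
        n, c, h, w = self._shape
        ho, wo = grad.shape[2], grad.shape[3]
        dx = np.zeros((n, c, h, w))
        up = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : ho * k, : wo * k] = up
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    # -- state (de)serialization -------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.parameters()):
                state[f"{i}.param{j}"] = p.value
            for name, buf in layer.buffers().items():
                state[f"{i}.{name}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("state dict keys do not match the network structure")
        for key, arr in own.items():
            if np.shape(state[key]) != arr.shape:
                raise ValueError(
                    f"state entry {key!r} has shape {np.shape(state[key])}, "
                    f"expected {arr.shape}: checkpoint does not match"
                )
            arr[...] = state[key]


def zero_grad(params: list[Parameter]) -> None:
    for p in params:
        p.grad[...] = 0.0


class Adam:
    """ADAM optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        zero_grad(self.params)

    # optimizer state travels with training snapshots so a revert is exact
    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src
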