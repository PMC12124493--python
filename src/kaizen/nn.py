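"""Minimal convolutional network layers with explicit backpropagation.

NumPy implementation of the handful of layers the single-cell autoencoder
needs: strided 2-D convolution, transposed convolution, ReLU, residual
blocks, and the Adam optimizer. Activations are channels-last
``(N, H, W, C)`` arrays so each convolution reduces to one contiguous
im2col copy plus one BLAS matrix product; the transposed convolution is the
exact adjoint (col2im scatter-add), so gradient identities hold to machine
precision and are finite-difference checked in the test suite.

Padding is a per-side 4-tuple ``(top, bottom, left, right)`` so the
asymmetric "same" padding a 4x4 stride-1 window needs is expressible.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "LeakyReLU",
    "ResidualBlock",
    "Sequential",
    "Adam",
]

Pad4 = Tuple[int, int, int, int]

# training runs in float32 (the step is memory-bandwidth bound); float64 is
# the default so finite-difference gradient checks stay tight
DEFAULT_DTYPE = np.float64


def _as_pad4(pad) -> Pad4:
    if isinstance(pad, int):
        return (pad, pad, pad, pad)
    pad = tuple(int(p) for p in pad)
    if len(pad) == 2:  # (vertical, horizontal)
        return (pad[0], pad[0], pad[1], pad[1])
    if len(pad) != 4:
        raise ValueError("pad must be int, (v, h) or (top, bottom, left, right)")
    return pad


class Parameter:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray, dtype=None):
        self.value = np.asarray(value, dtype=dtype or DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _pad_nhwc(x: np.ndarray, pad: Pad4) -> np.ndarray:
    pt, pb, pl, pr = pad
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))


def _im2col(x: np.ndarray, k: int, stride: int, pad: Pad4,
            window_last: bool = False) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Contiguous windows of a (N, H, W, C) image.

    Returns (cols, padded shape); cols is (N, Ho, Wo, C, k, k), or
    (N, Ho, Wo, k, k, C) when ``window_last`` is set.
    """
    xp = _pad_nhwc(x, pad)
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    if window_last:
        win = win.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(win), xp.shape


def _col2im(cols: np.ndarray, padded_shape: Tuple[int, ...], k: int,
            stride: int, pad: Pad4, window_last: bool = False) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add windows into a (N,H,W,C) image."""
    pt, pb, pl, pr = pad
    out = np.zeros(padded_shape, dtype=cols.dtype)
    ho, wo = cols.shape[1:3]
    for i in range(k):
        for j in range(k):
            piece = cols[:, :, :, i, j, :] if window_last else cols[:, :, :, :, i, j]
            out[:, i: i + stride * ho: stride, j: j + stride * wo: stride, :] += piece
    h = padded_shape[1] - pt - pb
    w = padded_shape[2] - pl - pr
    return out[:, pt: pt + h, pl: pl + w, :]


class Conv2d(Layer):
    """2-D convolution, stride ``stride``, weight (O, C, k, k)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad=0,
        rng: np.random.Generator | None = None,
        dtype=None,
    ):
        rng = np.random.default_rng() if rng is None else rng
        self.dtype = dtype or DEFAULT_DTYPE
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, k, k))
        self.weight = Parameter(w, dtype=self.dtype)
        self.bias = Parameter(np.zeros(out_channels), dtype=self.dtype)
        self.kernel_size = k
        self.stride = stride
        self.pad = _as_pad4(pad)
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def _wmat(self) -> np.ndarray:
        o = self.weight.value.shape[0]
        return self.weight.value.reshape(o, -1)  # (O, C*k*k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        cols, padded_shape = _im2col(x, self.kernel_size, self.stride, self.pad)
        n, ho, wo = cols.shape[:3]
        y = cols.reshape(n * ho * wo, -1) @ self._wmat().T
        y = y.reshape(n, ho, wo, -1)
        y += self.bias.value
        self._cache = (cols, padded_shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.asarray(dy, dtype=self.dtype)
        cols, padded_shape = self._cache
        n, ho, wo = cols.shape[:3]
        m = n * ho * wo
        dym = dy.reshape(m, -1)
        colm = cols.reshape(m, -1)
        self.weight.grad += (dym.T @ colm).reshape(self.weight.value.shape)
        self.bias.grad += dym.sum(axis=0)
        dcols = (dym @ self._wmat()).reshape(cols.shape)
        return _col2im(dcols, padded_shape, self.kernel_size, self.stride, self.pad)

    def out_size(self, size: int, axis: int = 0) -> int:
        pt, pb, pl, pr = self.pad
        p = pt + pb if axis == 0 else pl + pr
        return (size + p - self.kernel_size) // self.stride + 1


class ConvTranspose2d(Layer):
    """Exact adjoint of :class:`Conv2d` with the same kernel/stride/pad.

    Output side length is ``(in - 1) * stride + kernel - (pad_lo + pad_hi)``.
    Weight is stored as (C_in, k, k, O).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad=0,
        rng: np.random.Generator | None = None,
        dtype=None,
    ):
        rng = np.random.default_rng() if rng is None else rng
        self.dtype = dtype or DEFAULT_DTYPE
        k = kernel_size
        fan_in = in_channels * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_channels, k, k, out_channels))
        self.weight = Parameter(w, dtype=self.dtype)
        self.bias = Parameter(np.zeros(out_channels), dtype=self.dtype)
        self.kernel_size = k
        self.stride = stride
        self.pad = _as_pad4(pad)
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def out_size(self, size: int, axis: int = 0) -> int:
        pt, pb, pl, pr = self.pad
        p = pt + pb if axis == 0 else pl + pr
        return (size - 1) * self.stride + self.kernel_size - p

    def _wmat(self) -> np.ndarray:
        c = self.weight.value.shape[0]
        return self.weight.value.reshape(c, -1)  # (C_in, k*k*O)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        n, h, w, c = x.shape
        k = self.kernel_size
        pt, pb, pl, pr = self.pad
        o = self.weight.value.shape[-1]
        ho, wo = self.out_size(h, 0), self.out_size(w, 1)
        cols = (x.reshape(n * h * w, c) @ self._wmat()).reshape(n, h, w, k, k, o)
        y = _col2im(cols, (n, ho + pt + pb, wo + pl + pr, o), k, self.stride,
                    self.pad, window_last=True)
        y += self.bias.value
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.asarray(dy, dtype=self.dtype)
        x = self._cache
        n, h, w, c = x.shape
        win, _ = _im2col(dy, self.kernel_size, self.stride, self.pad,
                         window_last=True)  # (N, H, W, k, k, O)
        m = n * h * w
        winm = win.reshape(m, -1)
        xm = x.reshape(m, c)
        self.weight.grad += (xm.T @ winm).reshape(self.weight.value.shape)
        self.bias.grad += dy.sum(axis=(0, 1, 2))
        return (winm @ self._wmat().T).reshape(x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    """ReLU with a small negative slope so units cannot die permanently
    (sign-gradient L1 training is prone to collapsing sparse targets to
    the all-zero output)."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ResidualBlock(Layer):
    """ReLU -> 3x3 conv -> ReLU -> 1x1 conv, plus identity skip."""

    def __init__(self, channels: int, hidden: int | None = None,
                 rng: np.random.Generator | None = None, dtype=None):
        hidden = channels if hidden is None else hidden
        self.body = Sequential([
            ReLU(),
            Conv2d(channels, hidden, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            ReLU(),
            Conv2d(hidden, channels, 1, stride=1, pad=0, rng=rng, dtype=dtype),
        ])

    def parameters(self) -> List[Parameter]:
        return self.body.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def parameters(self) -> List[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
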