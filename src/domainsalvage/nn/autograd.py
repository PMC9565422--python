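"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal define-by-run tape sufficient for the convolutional generators,
critics and task networks in this package: each operation records a closure
that accumulates gradients into its inputs.  Arrays keep whatever dtype they
are given (float32 for training speed, float64 for gradient checks).
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "no_grad", "narrow", "concat", "conv2d",
    "zero_dilate", "avg_pool2d", "relu", "leaky_relu", "tanh", "sigmoid",
    "log", "instance_norm", "batch_norm", "cross_entropy",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable the tape inside the block (inference / detached passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, prev, backward):
        out = Tensor(data)
        tracked = tuple(p for p in prev if p.requires_grad) if _GRAD_ENABLED else ()
        if tracked:
            out.requires_grad = True
            out._prev = tracked
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported; multiply by a reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other):
        assert self.data.ndim == 2 and other.data.ndim == 2

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def square(self):
        def bwd(g):
            self._accum(2.0 * self.data * g)
        return Tensor._make(self.data ** 2, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accum(np.sign(self.data) * g)
        return Tensor._make(np.abs(self.data), (self,), bwd)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bwd(g):
            self._accum(g.reshape(orig))
        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                gg = np.expand_dims(gg, axes)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    # keep scalars in the partner tensor's dtype so float32 graphs stay float32
    if dtype is not None and arr.dtype != dtype and (arr.ndim == 0 or not np.issubdtype(arr.dtype, np.floating)):
        arr = arr.astype(dtype)
    return Tensor(arr)


# -- elementwise nonlinearities ----------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accum(g * mask)
    return Tensor._make(x.data * mask, (x,), bwd)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mult = np.where(x.data > 0, 1.0, slope).astype(x.dtype)

    def bwd(g):
        x._accum(g * mult)
    return Tensor._make(x.data * mult, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g):
        x._accum(g * (1.0 - out_data ** 2))
    return Tensor._make(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))
    return Tensor._make(out_data, (x,), bwd)


def log(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(g / x.data)
    return Tensor._make(np.log(x.data), (x,), bwd)


def narrow(x: Tensor, start: int, stop: int) -> Tensor:
    """View of rows [start:stop) along axis 0 (gradient scatters back)."""
    def bwd(g):
        gg = np.zeros_like(x.data)
        gg[start:stop] = g
        x._accum(gg)
    return Tensor._make(x.data[start:stop], (x,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


# -- convolution and pooling ---------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-d cross-correlation, NCHW layout, weight (F, C, KH, KW).

    Stride-1 convolutions with kernels of 5 or larger go through an FFT
    path (mathematically identical, cheaper than im2col at those sizes);
    everything else uses im2col + matrix multiplication.
    """
    B, C, H, W = x.data.shape
    F, Cw, KH, KW = w.data.shape
    assert C == Cw, f"channel mismatch {C} vs {Cw}"
    s, p = stride, padding
    if s == 1 and min(KH, KW) >= 5:
        return _conv2d_fft(x, w, b, p)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    OH = (H + 2 * p - KH) // s + 1
    OW = (W + 2 * p - KW) // s + 1
    win = sliding_window_view(xp, (KH, KW), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * OH * OW, C * KH * KW)
    wf = w.data.reshape(F, -1).T
    out = cols @ wf
    if b is not None:
        out += b.data
    out_data = out.reshape(B, OH, OW, F).transpose(0, 3, 1, 2)

    prev = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * OH * OW, F)
        if w.requires_grad:
            w._accum((cols.T @ g2).T.reshape(F, C, KH, KW))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ wf.T).reshape(B, OH, OW, C, KH, KW).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for ki in range(KH):
                for kj in range(KW):
                    dxp[:, :, ki:ki + s * OH:s, kj:kj + s * OW:s] += dcols[..., ki, kj]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)
    return Tensor._make(out_data, prev, bwd)


def _conv2d_fft(x: Tensor, w: Tensor, b: Tensor | None, p: int) -> Tensor:
    """Stride-1 cross-correlation via real FFTs.

    With transform size equal to the padded input, the valid-correlation
    outputs never wrap, so the circular theorem gives the exact linear
    result; dX and dW reuse the cached spectra.
    """
    B, C, H, W = x.data.shape
    F, _, KH, KW = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = H + 2 * p, W + 2 * p
    OH, OW = Hp - KH + 1, Wp - KW + 1
    Xf = np.fft.rfft2(xp, s=(Hp, Wp))                 # (B, C, Hp, Wp//2+1)
    Wf = np.fft.rfft2(w.data, s=(Hp, Wp))             # (F, C, ...)
    Of = np.einsum("bcij,fcij->bfij", Xf, Wf.conj(), optimize=True)
    out = np.fft.irfft2(Of, s=(Hp, Wp))[:, :, :OH, :OW].astype(x.dtype, copy=False)
    if b is not None:
        out = out + b.data.reshape(1, F, 1, 1)

    prev = (x, w) if b is None else (x, w, b)

    def bwd(g):
        Gf = np.fft.rfft2(g, s=(Hp, Wp))              # (B, F, ...)
        if w.requires_grad:
            # dW[u] = sum_n xp[n+u] g[n]  (correlation of xp with g)
            DWf = np.einsum("bfij,bcij->fcij", Gf.conj(), Xf, optimize=True)
            dw = np.fft.irfft2(DWf, s=(Hp, Wp))[:, :, :KH, :KW]
            w._accum(dw.astype(w.dtype, copy=False))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dXp = g (*) w  (linear convolution)
            DXf = np.einsum("bfij,fcij->bcij", Gf, Wf, optimize=True)
            dxp = np.fft.irfft2(DXf, s=(Hp, Wp))
            x._accum(dxp[:, :, p:p + H, p:p + W].astype(x.dtype, copy=False)
                     if p else dxp[:, :, :H, :W].astype(x.dtype, copy=False))
    return Tensor._make(out, prev, bwd)


def zero_dilate(x: Tensor, stride: int) -> Tensor:
    """Insert `stride-1` zeros between spatial elements (transposed-conv helper)."""
    B, C, H, W = x.data.shape
    s = stride
    out_data = np.zeros((B, C, (H - 1) * s + 1, (W - 1) * s + 1), dtype=x.dtype)
    out_data[:, :, ::s, ::s] = x.data

    def bwd(g):
        x._accum(g[:, :, ::s, ::s])
    return Tensor._make(out_data, (x,), bwd)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    B, C, H, W = x.data.shape
    assert H % k == 0 and W % k == 0
    out_data = x.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

    def bwd(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(gg)
    return Tensor._make(out_data, (x,), bwd)


# -- normalization -------------------------------------------------------------

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    B, C, H, W = x.data.shape
    n = H * W
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gb = gamma.data.reshape(1, C, 1, 1)
    out_data = gb * xhat + beta.data.reshape(1, C, 1, 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gb
            t1 = dxhat
            t2 = dxhat.mean(axis=(2, 3), keepdims=True)
            t3 = xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (t1 - t2 - t3))
    return Tensor._make(out_data, (x, gamma, beta), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, var: np.ndarray,
               training: bool, eps: float = 1e-5) -> Tensor:
    """1-d batch normalization; in training mode stats are batch statistics
    (and gradients flow through them), in eval mode they are the supplied
    running statistics treated as constants."""
    if training:
        mu = x.data.mean(axis=0)
        xc = x.data - mu
        v = (xc ** 2).mean(axis=0)
    else:
        mu, v = mean, var
        xc = x.data - mu
    inv = 1.0 / np.sqrt(v + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            if training:
                x._accum(inv * (dxhat - dxhat.mean(axis=0)
                                - xhat * (dxhat * xhat).mean(axis=0)))
            else:
                x._accum(dxhat * inv)
    return Tensor._make(out_data, (x, gamma, beta), bwd)


# -- classification loss -------------------------------------------------------

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of softmax(logits) at integer `labels`."""
    z = logits.data
    B = z.shape[0]
    labels = np.asarray(labels)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    logp = (z - zmax) - np.log(sez)
    loss = -logp[np.arange(B), labels].mean()

    def bwd(g):
        p = ez / sez
        p[np.arange(B), labels] -= 1.0
        logits._accum(p * (g / B))
    return Tensor._make(np.asarray(loss, dtype=z.dtype), (logits,), bwd)
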