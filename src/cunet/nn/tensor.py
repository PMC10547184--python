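"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the segmentation network needs:
broadcasting arithmetic, elementwise nonlinearities, reductions, 2-D
convolution (stride 1, odd kernels, same padding), 2x2 max pooling, bilinear
resizing and dropout.  Convolution is lowered to an im2col matrix product so
the heavy lifting runs through BLAS.  All arrays are float64.

Gradients are accumulated by a topological-order sweep over the recorded
graph, mirroring the familiar ``Tensor``/``backward`` idiom.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

DTYPE = np.float64


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._prev:
                    if id(p) not in seen:
                        stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._prev = tuple(parents)
        out._backward = backward
    return out


# -- arithmetic ------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bwd)


def sub(a, b):
    a, b = astensor(a), astensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bwd)


def mul(a, b):
    a, b = astensor(a), astensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bwd)


def div(a, b):
    a, b = astensor(a), astensor(b)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(a.data / b.data, (a, b), bwd)


def power(a, p: float):
    a = astensor(a)
    p = float(p)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * p * np.power(a.data, p - 1.0))

    return _make(np.power(a.data, p), (a,), bwd)


def log(a):
    a = astensor(a)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), bwd)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient passes only where the input is inside [lo, hi]."""
    a = astensor(a)
    inside = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * inside)

    return _make(np.clip(a.data, lo, hi), (a,), bwd)


def relu(a):
    a = astensor(a)
    mask = a.data > 0

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bwd)


def sigmoid(a):
    a = astensor(a)
    out_data = expit(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def tsum(a, axis=None, keepdims: bool = False):
    a = astensor(a)

    def bwd(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def tmean(a, axis=None, keepdims: bool = False):
    a = astensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def take(a, idx):
    a = astensor(a)

    def bwd(g):
        if a.requires_grad:
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accumulate(buf)

    return _make(a.data[idx], (a,), bwd)


def reshape(a, shape):
    a = astensor(a)
    old = a.shape

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd)


# -- spatial operations ----------------------------------------------------

def conv2d(x, w, b=None):
    """Same-padding stride-1 cross-correlation.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kh, kw; ``b``: (O,).
    """
    x, w = astensor(x), astensor(w)
    if b is not None:
        b = astensor(b)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel extents")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, c * kh * kw
    )
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, o)
        if w.requires_grad:
            w._accumulate((g2.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ wmat).reshape(n, h, wd, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j]
            x._accumulate(dxp[:, :, ph : ph + h, pw : pw + wd])

    parents = (x, w) if b is None else (x, w, b)
    return _make(np.ascontiguousarray(out), parents, bwd)


def maxpool2(x):
    """2x2 max pooling with stride 2; spatial sides must be even."""
    x = astensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 requires even sides, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))

    def bwd(g):
        if x.requires_grad:
            mask = xr == out[:, :, :, None, :, None]
            # split gradient evenly across ties so the pooled sum is conserved
            counts = mask.sum(axis=(3, 5), keepdims=True)
            gx = mask * (g[:, :, :, None, :, None] / counts)
            x._accumulate(gx.reshape(n, c, h, w))

    return _make(out, (x,), bwd)


_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    key = (n_in, n_out)
    mat = _RESIZE_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n_out, n_in), dtype=DTYPE)
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            f = int(np.floor(src))
            t = src - f
            f0 = min(max(f, 0), n_in - 1)
            f1 = min(max(f + 1, 0), n_in - 1)
            mat[i, f0] += 1.0 - t
            mat[i, f1] += t
        _RESIZE_CACHE[key] = mat
    return mat


def resize_bilinear(x, out_h: int, out_w: int):
    """Bilinear resize of (N, C, H, W) maps to (out_h, out_w)."""
    x = astensor(x)
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _resize_matrix(h, out_h)
    aw = _resize_matrix(w, out_w)
    out = ah @ x.data @ aw.T

    def bwd(g):
        if x.requires_grad:
            x._accumulate(ah.T @ g @ aw)

    return _make(out, (x,), bwd)


def dropout(x, p: float, rng: np.random.Generator, training: bool):
    x = astensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return _make(x.data * keep, (x,), bwd)
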