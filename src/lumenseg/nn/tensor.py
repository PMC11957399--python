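"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed for small trainable 3-D
convolutional networks: broadcasting arithmetic, reductions, ReLU /
elementwise min & max, channel softmax, stride-1 "same" 3-D convolution,
2x2x2 transposed convolution, block max-pooling, per-axis linear maps
(used for trilinear upsampling) and edge-clamped shifts (used for soft
morphology).  Tensors hold float32 data; gradients are accumulated in
``.grad`` by :meth:`Tensor.backward` via topological sort.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "minimum", "maximum", "relu",
           "conv3d", "conv_transpose3d", "maxpool3d", "axis_linmap",
           "shift_clamp", "softmax_channel", "take_index", "narrow",
           "batchnorm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, prev, backward, requires_grad):
        t = Tensor(data)
        if requires_grad:
            t.requires_grad = True
            t._prev = tuple(p for p in prev if isinstance(p, Tensor))
            t._backward = backward
        return t

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        topo, seen = [], set()

        def build(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                build(p)
            topo.append(t)

        build(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), back, rq)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), back, rq)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        rq = self.requires_grad
        a = self

        def back(g):
            a._accum(g * p * np.power(a.data, p - 1.0))

        return Tensor._make(np.power(self.data, p), (self,), back, rq)

    def exp(self):
        out_data = np.exp(self.data)
        a = self

        def back(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (self,), back, self.requires_grad)

    def log(self):
        a = self

        def back(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), back, self.requires_grad)

    # -- reductions / shape --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def back(g):
            if axis is None:
                ga = np.broadcast_to(g, a.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                ga = np.broadcast_to(gg, a.shape)
            a._accum(np.ascontiguousarray(ga))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), back, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = self.shape

        def back(g):
            a._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), back,
                            self.requires_grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def back(g):
        x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), back, x.requires_grad)


def _minmax(a: Tensor, b: Tensor, use_max: bool) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    rq = a.requires_grad or b.requires_grad
    pick_a = (a.data >= b.data) if use_max else (a.data <= b.data)
    out = np.where(pick_a, a.data, b.data)

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * pick_a, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~pick_a), b.shape))

    return Tensor._make(out, (a, b), back, rq)


def maximum(a, b) -> Tensor:
    return _minmax(a, b, True)


def minimum(a, b) -> Tensor:
    return _minmax(a, b, False)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    rq = any(t.requires_grad for t in tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, gg in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(gg))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), back, rq)


def shift_clamp(x: Tensor, axis: int, delta: int) -> Tensor:
    """Shift along ``axis`` by ``delta`` with edge replication."""
    x = as_tensor(x)
    n = x.shape[axis]
    idx = np.clip(np.arange(n) + delta, 0, n - 1)

    def back(g):
        gx = np.zeros_like(x.data)
        gx_m = np.moveaxis(gx, axis, 0)
        np.add.at(gx_m, idx, np.moveaxis(g, axis, 0))
        x._accum(gx)

    return Tensor._make(np.take(x.data, idx, axis=axis), (x,), back,
                        x.requires_grad)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice [start, start+length) along ``axis``."""
    x = as_tensor(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + length)

    def back(g):
        gx = np.zeros_like(x.data)
        gx[tuple(sl)] = g
        x._accum(gx)

    return Tensor._make(x.data[tuple(sl)], (x,), back, x.requires_grad)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over axes (0, 2, 3, 4).

    Returns (out, batch_mean, batch_var) with the statistics as plain
    arrays of shape (C,).  gamma/beta are (C,).
    """
    x = as_tensor(x)
    axes = (0, 2, 3, 4)
    c = x.shape[1]
    shape = (1, c, 1, 1, 1)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gsh = gamma.data.reshape(shape)
    out = gsh * xhat + beta.data.reshape(shape)
    rq = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def back(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gmean = g.mean(axis=axes, keepdims=True)
            gxhat_mean = (g * xhat).mean(axis=axes, keepdims=True)
            x._accum((gsh * inv) * (g - gmean - xhat * gxhat_mean))

    t = Tensor._make(out, (x, gamma, beta), back, rq)
    return t, mu.reshape(c), var.reshape(c)


def take_index(x: Tensor, index: int, axis: int) -> Tensor:
    """Select one index along ``axis`` (the axis is dropped)."""
    x = as_tensor(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = index

    def back(g):
        gx = np.zeros_like(x.data)
        gx[tuple(sl)] = g
        x._accum(gx)

    return Tensor._make(x.data[tuple(sl)], (x,), back, x.requires_grad)


def softmax_channel(x: Tensor) -> Tensor:
    """Numerically stable softmax over axis 1 (channels)."""
    x = as_tensor(x)
    shiftc = Tensor(x.data.max(axis=1, keepdims=True))  # constant, no grad
    e = (x - shiftc).exp()
    return e / e.sum(axis=1, keepdims=True)


# -- structured ops ----------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, zero-padded 'same' 3-D convolution (cross-correlation).

    ``x``: (N, C, D, H, W); ``w``: (O, C, k, k, k) with odd cubic ``k``;
    ``b``: (O,) or None.  The k == 1 case short-circuits to a channel mix.
    """
    x, w = as_tensor(x), as_tensor(w)
    k = w.shape[2]
    rq = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    if k == 1:
        w2 = w.data.reshape(w.shape[0], w.shape[1])
        out = np.einsum("oc,ncdhw->nodhw", w2, x.data, optimize=True)
        if b is not None:
            out = out + b.data[None, :, None, None, None]

        def back1(g):
            if w.requires_grad:
                gw = np.einsum("nodhw,ncdhw->oc", g, x.data, optimize=True)
                w._accum(gw.reshape(w.shape))
            if x.requires_grad:
                x._accum(np.einsum("oc,nodhw->ncdhw", w2, g, optimize=True))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3, 4)))

        prev = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, prev, back1, rq)

    p = k // 2
    pad = [(0, 0), (0, 0), (p, p), (p, p), (p, p)]
    xp = np.pad(x.data, pad)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    out = np.einsum("ncdhwijk,ocijk->nodhw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None, None]

    def back(g):
        if w.requires_grad:
            w._accum(np.einsum("ncdhwijk,nodhw->ocijk", win, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gp = np.pad(g, pad)
            gwin = np.lib.stride_tricks.sliding_window_view(
                gp, (k, k, k), axis=(2, 3, 4))
            wf = w.data[:, :, ::-1, ::-1, ::-1]
            x._accum(np.einsum("nodhwijk,ocijk->ncdhw", gwin, wf,
                               optimize=True))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, prev, back, rq)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Kernel-2, stride-2 transposed convolution (doubles each spatial axis).

    ``x``: (N, C, D, H, W); ``w``: (C, O, 2, 2, 2).
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, D, H, W = x.shape
    O = w.shape[1]
    rq = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    t = np.einsum("ncdhw,coijk->nodihjwk", x.data, w.data, optimize=True)
    out = t.reshape(N, O, 2 * D, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data[None, :, None, None, None]

    def back(g):
        gr = g.reshape(N, O, D, 2, H, 2, W, 2)
        if w.requires_grad:
            w._accum(np.einsum("ncdhw,nodihjwk->coijk", x.data, gr,
                               optimize=True))
        if x.requires_grad:
            x._accum(np.einsum("nodihjwk,coijk->ncdhw", gr, w.data,
                               optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, prev, back, rq)


def maxpool3d(x: Tensor, factors=(2, 2, 2)) -> Tensor:
    """Non-overlapping block max pooling; spatial axes must divide evenly."""
    x = as_tensor(x)
    N, C, D, H, W = x.shape
    fd, fh, fw = factors
    if D % fd or H % fh or W % fw:
        raise ValueError(f"shape {(D, H, W)} not divisible by pool factors {factors}")
    xr = x.data.reshape(N, C, D // fd, fd, H // fh, fh, W // fw, fw)
    out = xr.max(axis=(3, 5, 7))
    oexp = out[:, :, :, None, :, None, :, None]
    mask = (xr == oexp)
    cnt = mask.sum(axis=(3, 5, 7), keepdims=True)
    route = mask / cnt  # split gradient across ties

    def back(g):
        gexp = g.reshape(N, C, D // fd, 1, H // fh, 1, W // fw, 1)
        x._accum((route * gexp).reshape(x.shape))

    return Tensor._make(out, (x,), back, x.requires_grad)


def axis_linmap(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply a fixed linear map ``m`` (out_n, in_n) along one axis."""
    x = as_tensor(x)

    def apply(mat, arr):
        moved = np.moveaxis(arr, axis, 0)
        res = np.tensordot(mat, moved, axes=(1, 0))
        return np.moveaxis(res, 0, axis)

    def back(g):
        x._accum(np.ascontiguousarray(apply(m.T, g)).astype(np.float32))

    return Tensor._make(apply(m, x.data), (x,), back, x.requires_grad)


def upsample_matrix(n: int, factor: int) -> np.ndarray:
    """1-D linear-interpolation matrix (n*factor, n), align_corners=False.

    factor == 1 returns the identity.  Output sample o maps to input
    coordinate (o + 0.5)/factor - 0.5, clamped at the edges.
    """
    if factor == 1:
        return np.eye(n, dtype=np.float32)
    m = np.zeros((n * factor, n), dtype=np.float32)
    for o in range(n * factor):
        u = (o + 0.5) / factor - 0.5
        i0 = int(np.floor(u))
        frac = u - i0
        i0c = min(max(i0, 0), n - 1)
        i1c = min(max(i0 + 1, 0), n - 1)
        m[o, i0c] += 1.0 - frac
        m[o, i1c] += frac
    return m
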