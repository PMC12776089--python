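"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set the synthesis network needs: broadcasting
arithmetic, matmul, stride-1 'same' 3D convolution (shared and per-sample
kernels), 2x average pooling / nearest upsampling, channel concatenation,
elementwise nonlinearities, axis reductions and gather-along-axis-0.
Everything is float64; gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "concat", "conv3d", "conv3d_persample",
    "avg_pool3d_2", "upsample3d_2", "take0", "relu", "exp", "log",
    "sigmoid", "softmax",
]


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
                # free intermediate grads/graph refs eagerly
                if not t.requires_grad and t is not self:
                    t.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: _unbroadcast(g, a.shape),
                       lambda g, a, b: _unbroadcast(g, b.shape))

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.data, _parents=(a,), _backward=None)

        def back(g):
            if _tracked(a):
                a._accumulate(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: _unbroadcast(g * b.data, a.shape),
                       lambda g, a, b: _unbroadcast(g * a.data, b.shape))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float):
        a = self
        out = Tensor(a.data ** p, _parents=(a,))

        def back(g):
            if _tracked(a):
                a._accumulate(g * p * a.data ** (p - 1.0))

        out._backward = back
        return out

    def __matmul__(self, other):
        a, b = self, as_tensor(other)
        out = Tensor(a.data @ b.data, _parents=(a, b))

        def back(g):
            if _tracked(a):
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape))
            if _tracked(b):
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        out._backward = back
        return out

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

        def back(g):
            if not _tracked(a):
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis if isinstance(axis, int) else tuple(axis))
            a._accumulate(np.broadcast_to(gg, a.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        out = Tensor(a.data.reshape(*shape), _parents=(a,))

        def back(g):
            if _tracked(a):
                a._accumulate(g.reshape(a.shape))

        out._backward = back
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _tracked(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, back_a, back_b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), _parents=(a, b))

    def back(g):
        if _tracked(a):
            a._accumulate(back_a(g, a, b))
        if _tracked(b):
            b._accumulate(back_b(g, a, b))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    # subgradient 1 at exactly 0, so zero-initialized residual paths (which
    # park activations on 0) keep a live gradient
    x = as_tensor(x)
    mask = x.data >= 0
    out = Tensor(np.where(mask, x.data, 0.0), _parents=(x,))

    def back(g):
        if _tracked(x):
            x._accumulate(g * mask)

    out._backward = back
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = np.exp(x.data)
    out = Tensor(val, _parents=(x,))

    def back(g):
        if _tracked(x):
            x._accumulate(g * val)

    out._backward = back
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), _parents=(x,))

    def back(g):
        if _tracked(x):
            x._accumulate(g / x.data)

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(val, _parents=(x,))

    def back(g):
        if _tracked(x):
            x._accumulate(g * val * (1.0 - val))

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max; softmax is shift-invariant so the gradient is exact
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if _tracked(t):
                t._accumulate(p)

    out._backward = back
    return out


def take0(x: Tensor, indices) -> Tensor:
    """Gather rows of x along axis 0 (e.g. prompt-bank selection per subject)."""
    x = as_tensor(x)
    idx = np.asarray(indices, dtype=np.intp)
    out = Tensor(x.data[idx], _parents=(x,))

    def back(g):
        if _tracked(x):
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# 3D convolution (stride 1, odd kernel, 'same' zero padding)
# ---------------------------------------------------------------------------

def _corr3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    """x (N,Ci,D,H,W), w (Co,Ci,k,k,k) -> out (N,Co,D,H,W), plus im2col matrix."""
    n, ci, d, h, wd = x.shape
    co, _, k, _, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (N,Ci,D,H,W,k,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(n, d * h * wd, ci * k ** 3)
    out = cols @ w.reshape(co, -1).T
    if b is not None:
        out = out + b
    return out.transpose(0, 2, 1).reshape(n, co, d, h, wd), cols


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 3D correlation with shared kernel w (Co,Ci,k,k,k)."""
    x, w = as_tensor(x), as_tensor(w)
    if w.shape[1] != x.shape[1]:
        raise ValueError(f"conv3d channel mismatch: input {x.shape[1]}, kernel expects {w.shape[1]}")
    if w.shape[-1] % 2 != 1:
        raise ValueError("conv3d requires an odd kernel size")
    bdat = None if b is None else b.data
    val, cols = _corr3d_raw(x.data, w.data, bdat)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, _parents=parents)
    n, co, d, h, wd = val.shape

    def back(g):
        gmat = g.reshape(n, co, d * h * wd).transpose(0, 2, 1)  # (N, DHW, Co)
        if b is not None and _tracked(b):
            b._accumulate(gmat.sum(axis=(0, 1)))
        if _tracked(w):
            gw = np.einsum("npc,npk->ck", gmat, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape))
        if _tracked(x):
            # adjoint of 'same' correlation: correlate with spatially flipped,
            # channel-swapped kernel
            wt = np.ascontiguousarray(w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            gx, _ = _corr3d_raw(g, wt, None)
            x._accumulate(gx)

    out._backward = back
    return out


def conv3d_persample(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Like conv3d but with one kernel per sample: w (N,Co,Ci,k,k,k).

    Used by the conditionally parameterized upsampling convolutions, where the
    kernel is a per-subject mixture of expert kernels.
    """
    x, w = as_tensor(x), as_tensor(w)
    n = x.shape[0]
    if w.shape[0] != n:
        raise ValueError("conv3d_persample: batch dims of input and kernels differ")
    bdat = None if b is None else b.data
    outs, cols_list = [], []
    for i in range(n):
        o, c = _corr3d_raw(x.data[i:i + 1], w.data[i], bdat)
        outs.append(o)
        cols_list.append(c)
    val = np.concatenate(outs, axis=0)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(val, _parents=parents)
    _, co, d, h, wd = val.shape

    def back(g):
        if b is not None and _tracked(b):
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gw = np.empty_like(w.data) if _tracked(w) else None
        gx = np.empty_like(x.data) if _tracked(x) else None
        for i in range(n):
            gmat = g[i].reshape(co, d * h * wd).T  # (DHW, Co)
            if gw is not None:
                gw[i] = (gmat.T @ cols_list[i][0]).reshape(w.shape[1:])
            if gx is not None:
                wt = np.ascontiguousarray(w.data[i][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
                gxi, _ = _corr3d_raw(g[i:i + 1], wt, None)
                gx[i] = gxi[0]
        if gw is not None:
            w._accumulate(gw)
        if gx is not None:
            x._accumulate(gx)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# resolution changes (factor-2)
# ---------------------------------------------------------------------------

def avg_pool3d_2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avg_pool3d_2 needs even spatial dims, got {(d, h, w)}")
    val = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))
    out = Tensor(val, _parents=(x,))

    def back(g):
        if _tracked(x):
            gg = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
            x._accumulate(gg)

    out._backward = back
    return out


def upsample3d_2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by 2 along each spatial axis."""
    x = as_tensor(x)
    val = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)
    out = Tensor(val, _parents=(x,))
    n, c, d, h, w = x.shape

    def back(g):
        if _tracked(x):
            gg = g.reshape(n, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))
            x._accumulate(gg)

    out._backward = back
    return out
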