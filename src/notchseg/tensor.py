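"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's CPU tensor engine.  It implements exactly the
operations the segmentation network needs -- elementwise arithmetic,
matmul, 2D (depthwise) convolution, pooling, bilinear resizing, softmax
-- each with a hand-written backward rule.  Arrays are float64
throughout; at the problem sizes this package targets (2D slices up to a
few hundred pixels) the double-precision BLAS path is fast enough and
keeps numerical test tolerances tight.

Gradients are accumulated by a topological-order sweep from the output
(`Tensor.backward`).  Graph construction is skipped entirely when no
input requires gradients or inside `no_grad()`, so evaluation-mode
forward passes carry no autodiff overhead.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction within the context (evaluation mode)."""
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
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            sa, sb = self.data.shape, other.data.shape
            out._backward = lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )
        return out

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
        out = _make(self.data**p, (self,))
        if out._parents:
            a = self
            out._backward = lambda g: (g * p * a.data ** (p - 1.0),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out._parents:
            a, b = self, other
            out._backward = lambda g: (
                _unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape),
                _unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape),
            )
        return out

    # -- shaping ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g: (g.reshape(old),)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        """Basic (slice/int) indexing only; duplicates are not supported."""
        out = _make(self.data[idx], (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g):
                full = np.zeros(shape, dtype=np.float64)
                full[idx] += g
                return (full,)

            out._backward = bw
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.data.shape

            def bw(g):
                if axis is None:
                    return (np.broadcast_to(g, shape).copy(),)
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                return (np.broadcast_to(g, shape).copy(),)

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out._parents:
            mask = self.data > 0
            out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        x = self.data
        s = np.where(
            x >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x))),
            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
        )
        out = _make(s, (self,))
        if out._parents:
            out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _make(e, (self,))
        if out._parents:
            out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            a = self
            out._backward = lambda g: (g / a.data,)
        return out

    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out._parents:
            s = np.sign(self.data)
            out._backward = lambda g: (g * s,)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _make(s, (self,))
        if out._parents:
            out._backward = lambda g: (s * (g - (g * s).sum(axis=axis, keepdims=True)),)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(
        p.requires_grad or p._parents for p in parents if isinstance(p, Tensor)
    ):
        out._parents = parents
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        out._backward = lambda g: tuple(
            np.take(g, i, axis=axis) for i in range(len(tensors))
        )
    return out


def pad_reflect(x: Tensor, pad_h: int, pad_w: int) -> Tensor:
    """Reflect-pad the trailing edge of the last two axes (NCHW)."""
    if pad_h == 0 and pad_w == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(0, pad_h), (0, pad_w)]
    out = _make(np.pad(x.data, width, mode="reflect"), (x,))
    if out._parents:
        H, W = x.data.shape[-2], x.data.shape[-1]

        def bw(g):
            core = g[..., :H, :W].copy()
            # reflected rows/cols fold their gradient back onto the source
            if pad_h:
                core[..., H - 1 - pad_h : H - 1, :] += g[..., H:, :W][..., ::-1, :]
            if pad_w:
                core[..., :, W - 1 - pad_w : W - 1] += g[..., :H, W:][..., :, ::-1]
            if pad_h and pad_w:
                core[..., H - 1 - pad_h : H - 1, W - 1 - pad_w : W - 1] += g[
                    ..., H:, W:
                ][..., ::-1, ::-1]
            return (core,)

        out._backward = bw
    return out


# -- spatial operations ---------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2D cross-correlation, NCHW input, OIHW weight."""
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    wmat = w.data.reshape(O, -1)
    out_flat = cols @ wmat.T
    if b is not None:
        out_flat = out_flat + b.data
    out_data = out_flat.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._parents:
        Hp, Wp = xp.shape[2], xp.shape[3]

        def bw(g):
            gcols_o = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
            gw = (gcols_o.T @ cols).reshape(O, C, kh, kw)
            gcols = (gcols_o @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            gxp = np.zeros((N, C, Hp, Wp), dtype=np.float64)
            gc = gcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,kh,kw
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho * stride : stride,
                        j : j + Wo * stride : stride] += gc[:, :, :, :, i, j]
            gx = gxp[:, :, padding : Hp - padding or None,
                     padding : Wp - padding or None]
            if b is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        out._backward = bw
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     padding: int = 0) -> Tensor:
    """Per-channel 2D convolution; weight shape (C, kh, kw), stride 1."""
    N, C, H, W = x.data.shape
    Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"depthwise channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    Ho, Wo = win.shape[2], win.shape[3]
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents)
    if out._parents:
        Hp, Wp = xp.shape[2], xp.shape[3]

        def bw(g):
            gw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
            gxp = np.zeros((N, C, Hp, Wp), dtype=np.float64)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho, j : j + Wo] += (
                        g * w.data[:, i, j][None, :, None, None]
                    )
            gx = gxp[:, :, padding : Hp - padding or None,
                     padding : Wp - padding or None]
            if b is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide by k."""
    if k == 1:
        return x
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims ({H},{W}) not divisible by {k}")
    out_data = x.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))
    out = _make(out_data, (x,))
    if out._parents:
        out._backward = lambda g: (
            np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k),
        )
    return out


def _linear_interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic matrix mapping n_in samples to n_out (bilinear, half-pixel
    centers)."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the last two axes of an NCHW tensor."""
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    A = _linear_interp_matrix(out_h, H)
    B = _linear_interp_matrix(out_w, W)
    out_data = np.matmul(np.matmul(A, x.data), B.T)
    out = _make(out_data, (x,))
    if out._parents:
        out._backward = lambda g: (np.matmul(np.matmul(A.T, g), B),)
    return out
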