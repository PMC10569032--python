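"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small and fixed-topology, so a
compact tape-based autograd over float32 numpy arrays (BLAS-backed matmul,
offset-decomposed convolutions) is all the training loop needs.  The public
surface is the :class:`Tensor` class plus a handful of primitive operations;
neural-network layers live in :mod:`swunet.nn`.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy import special as _sp

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float32)

        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): grad}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, backward):
    """Build an op output; ``backward(g)`` yields (parent, parent_grad) pairs."""
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None for p in parents):
        out = Tensor(data)
        out.requires_grad = False
        out._parents = tuple(parents)
        out._backward = backward
        return out
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(out, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _make(out, (a, b), backward)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data / b.data

    def backward(g):
        return (
            (a, _unbroadcast(g / b.data, a.data.shape)),
            (b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        )

    return _make(out, (a, b), backward)


def power(a, p: float):
    a = _wrap(a)
    out = a.data ** p

    def backward(g):
        return ((a, g * p * a.data ** (p - 1.0)),)

    return _make(out, (a,), backward)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return ((a, _unbroadcast(ga, a.data.shape)), (b, _unbroadcast(gb, b.data.shape)))

    return _make(out, (a, b), backward)


def reshape(a, shape):
    a = _wrap(a)
    out = a.data.reshape(shape)

    def backward(g):
        return ((a, g.reshape(a.data.shape)),)

    return _make(out, (a,), backward)


def transpose(a, axes):
    a = _wrap(a)
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return ((a, g.transpose(inv)),)

    return _make(out, (a,), backward)


def take(a, idx):
    a = _wrap(a)
    out = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    return _make(out, (a,), backward)


def concatenate(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        return tuple(zip(tensors, pieces))

    return _make(out, tuple(tensors), backward)


def roll(a, shift, axes):
    a = _wrap(a)
    out = np.roll(a.data, shift, axis=axes)
    neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift

    def backward(g):
        return ((a, np.roll(g, neg, axis=axes)),)

    return _make(out, (a,), backward)


def flip(a, axes):
    a = _wrap(a)
    out = np.flip(a.data, axis=axes)

    def backward(g):
        return ((a, np.flip(g, axis=axes)),)

    return _make(out, (a,), backward)


def pad(a, pad_width):
    """Zero padding; ``pad_width`` as for np.pad."""
    a = _wrap(a)
    out = np.pad(a.data, pad_width)
    slices = tuple(slice(lo, lo + n) for (lo, _), n in zip(pad_width, a.data.shape))

    def backward(g):
        return ((a, g[slices]),)

    return _make(out, (a,), backward)


def zero_upsample2d(a, stride: int):
    """Insert ``stride - 1`` zeros between elements along the last two axes."""
    a = _wrap(a)
    *lead, h, w = a.data.shape
    out = np.zeros((*lead, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=np.float32)
    out[..., ::stride, ::stride] = a.data

    def backward(g):
        return ((a, g[..., ::stride, ::stride]),)

    return _make(out, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g, dtype=np.float32)
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else axis
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        return ((a, np.broadcast_to(g, a.data.shape).copy()),)

    return _make(out, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def exp(a):
    a = _wrap(a)
    out = np.exp(a.data)

    def backward(g):
        return ((a, g * out),)

    return _make(out, (a,), backward)


def log(a):
    a = _wrap(a)
    out = np.log(a.data)

    def backward(g):
        return ((a, g / a.data),)

    return _make(out, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    out = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return ((a, g * out * (1.0 - out)),)

    return _make(out, (a,), backward)


def relu(a):
    a = _wrap(a)
    out = np.maximum(a.data, 0.0)

    def backward(g):
        return ((a, g * (a.data > 0)),)

    return _make(out, (a,), backward)


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a):
    """Exact (erf-based) Gaussian error linear unit."""
    a = _wrap(a)
    phi = 0.5 * (1.0 + _sp.erf(a.data * _INV_SQRT2))
    out = a.data * phi

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        return ((a, g * (phi + a.data * pdf).astype(np.float32)),)

    return _make(out.astype(np.float32), (a,), backward)


def clip(a, lo: float, hi: float):
    """Clip values; gradient passes only through the interior."""
    a = _wrap(a)
    out = np.clip(a.data, lo, hi)

    def backward(g):
        inside = (a.data >= lo) & (a.data <= hi)
        return ((a, g * inside),)

    return _make(out, (a,), backward)


def softmax(a, axis=-1):
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((a, out * (g - dot)),)

    return _make(out, (a,), backward)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D convolution (cross-correlation) over NCHW input.

    Decomposed into one GEMM per kernel offset, which keeps memory traffic low
    for the small 3x3 kernels used throughout the model.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    B, Ci, H, W = x.data.shape
    Co, Ciw, kh, kw = w.data.shape
    if Ci != Ciw:
        raise ValueError(f"conv2d channel mismatch: input has {Ci}, weight expects {Ciw}")
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    acc = np.zeros((Co, B, Ho, Wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            patch = xp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s]
            acc += np.tensordot(w.data[:, :, ki, kj], patch, axes=([1], [1]))
    out = acc.transpose(1, 0, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1)

    def backward(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for ki in range(kh):
            for kj in range(kw):
                patch = xp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s]
                gw[:, :, ki, kj] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += np.tensordot(
                    w.data[:, :, ki, kj], g, axes=([0], [1])
                ).transpose(1, 0, 2, 3)
        gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
        pairs = [(x, gx), (w, gw)]
        if b is not None:
            pairs.append((b, g.sum(axis=(0, 2, 3))))
        return tuple(pairs)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)
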