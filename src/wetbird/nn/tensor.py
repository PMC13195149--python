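"""Reverse-mode automatic differentiation over numpy arrays.

A tape-free, graph-walking autograd in the micrograd style, but array-valued
and restricted to the operations a convolutional detector needs.  All tensors
are float32; gradients are accumulated in float32 as well.
"""
from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    # evaluate via exp of a non-positive argument to avoid overflow
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "trainable", "name")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()
        self.trainable = requires_grad  # parameter flag; buffers set this False
        self.name = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, prev, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

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
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff driver ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph bookkeeping as we go
                node._backward = None
                node._prev = ()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g) if a.requires_grad else None)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._make(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def sigmoid(self):
        a = self
        s = _stable_sigmoid(a.data)
        return Tensor._make(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def silu(self):
        a = self
        s = _stable_sigmoid(a.data)
        return Tensor._make(a.data * s, (a,), lambda g: a._accum(g * (s * (1.0 + a.data * (1.0 - s)))))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def arctan(self):
        a = self
        return Tensor._make(np.arctan(a.data), (a,), lambda g: a._accum(g / (1.0 + a.data * a.data)))

    def clip(self, lo, hi):
        a = self
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: a._accum(g * mask))

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            gg, oo = g, out_data
            if not keepdims:
                gg = np.expand_dims(gg, axis)
                oo = np.expand_dims(oo, axis)
            mask = (a.data == oo)
            cnt = mask.sum(axis=axis, keepdims=True)
            a._accum(mask * (gg / cnt))

        return Tensor._make(out_data, (a,), bw)

    def softmax(self, axis):
        z = self - self.max(axis=axis, keepdims=True).detach()
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: a._accum(g.reshape(old)))

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,),
                            lambda g: a._accum(g.transpose(tuple(inv))))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, idx, g)
            a._accum(buf)

        return Tensor._make(a.data[idx], (a,), bw)

    def pad2d(self, pt, pb, pl, pr, value=0.0):
        """Zero-pad the last two axes of an [..., H, W] tensor."""
        a = self
        width = [(0, 0)] * (a.data.ndim - 2) + [(pt, pb), (pl, pr)]
        out_data = np.pad(a.data, width, constant_values=value)
        H, W = a.data.shape[-2:]

        def bw(g):
            sl = (Ellipsis, slice(pt, pt + H), slice(pl, pl + W))
            a._accum(g[sl])

        return Tensor._make(out_data, (a,), bw)


def concat(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, s in zip(tensors, offs[:-1], sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o, o + s)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def stack(tensors, axis=0):
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bw)


def where_const(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select between two tensors with a constant boolean mask."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * cond, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~cond), b.data.shape))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), bw)
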