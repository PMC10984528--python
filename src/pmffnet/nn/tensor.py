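"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small, CPU-oriented engine: a :class:`Tensor` wraps a float32
numpy array and records, for every differentiable operation, the parent
tensors and a closure that maps the upstream gradient to parent gradients.
``backward()`` runs a topological sweep over that graph.  Heavy fused kernels
(convolution, normalization, attention primitives) live in
:mod:`pmffnet.nn.functional`; this module provides the graph machinery and
the elementwise / shape operations.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate graph state eagerly
                node._backward = None
                node._parents = ()

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                _accum(self, g)
                _accum(other, g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                _accum(self, g * other.data)
                _accum(other, g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                _accum(self, g / other.data)
                _accum(other, -g * out.data / other.data)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(
                self, g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out.requires_grad:
            def bw(g):
                _accum(self, np.matmul(g, np.swapaxes(other.data, -1, -2)))
                _accum(other, np.matmul(np.swapaxes(self.data, -1, -2), g))
            out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g * out.data)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g / self.data)
        return out

    def sigmoid(self):
        out = _make(_sigmoid(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g * out.data * (1.0 - out.data))
        return out

    def silu(self):
        """x * sigmoid(x) — the SiLU / swish activation."""
        sig = _sigmoid(self.data)
        out = _make(self.data * sig, (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(
                self, g * sig * (1.0 + self.data * (1.0 - sig)))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only inside the open interval."""
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
            out._backward = lambda g: _accum(self, g * mask)
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = _make(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out.requires_grad:
            out._backward = lambda g: _accum(self, g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out.requires_grad:
            def bw(g):
                gx = np.zeros_like(self.data)
                np.add.at(gx, key, g)
                _accum(self, gx)
            out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    t = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        t.requires_grad = True
        t._parents = tuple(parents)
    return t


def _accum(p: Tensor, g: np.ndarray):
    if not p.requires_grad:
        return
    g = _unbroadcast(np.asarray(g, dtype=np.float32), p.data.shape)
    p.grad = g if p.grad is None else p.grad + g


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                _accum(t, piece)
        out._backward = bw
    return out


def pad2d(x: Tensor, pad: tuple) -> Tensor:
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out = _make(np.pad(x.data, width), (x,))
    if out.requires_grad:
        sl = tuple([slice(None)] * (x.ndim - 2)
                   + [slice(t, out.shape[-2] - b), slice(l, out.shape[-1] - r)])
        out._backward = lambda g: _accum(x, g[sl])
    return out
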