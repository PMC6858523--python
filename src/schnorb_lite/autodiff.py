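"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the network in :mod:`schnorb_lite.model`:
elementwise arithmetic with broadcasting, 2-D matrix products, reductions,
gather/scatter, and the handful of nonlinearities the architecture uses.

Backward functions are themselves built from these primitives, so the graph of a
gradient is again differentiable.  That is what allows the force term of the
training loss -- which contains dE/dr, itself a gradient -- to be differentiated
with respect to the network parameters (double backprop).

Only float64 is supported; shapes are whatever numpy broadcasting allows for the
elementwise ops, while :func:`matmul` is restricted to 2-D operands.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "constant", "grad",
    "add", "mul", "matmul", "tsum", "reshape", "transpose",
    "exp", "log", "sqrt", "cos", "sin", "softplus", "sigmoid",
    "take", "scatter_add", "take2", "scatter_add2",
]


class Tensor:
    """A node in the computation graph: a float64 array plus its provenance."""

    __slots__ = ("value", "parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents          # tuple of (parent Tensor, vjp: Tensor -> Tensor)
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, constant(-1.0))

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"


def tensor(value):
    """A differentiable leaf."""
    return Tensor(value, requires_grad=True)


def constant(value):
    """A non-differentiable graph constant."""
    return Tensor(value)


def _wrap(x):
    return x if isinstance(x, Tensor) else constant(x)


def _node(value, parents):
    req = any(p.requires_grad for p, _ in parents)
    return Tensor(value, tuple(parents) if req else (), req)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.value.shape == shape:
        return g
    extra = g.value.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.value.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.value.shape != shape:
        g = reshape(g, shape)
    return g


# -- primitives ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.value + b.value, [
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(g, b.value.shape)),
    ])


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.value * b.value, [
        (a, lambda g: _unbroadcast(mul(g, b), a.value.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.value.shape)),
    ])


def power(a: Tensor, p: float) -> Tensor:
    out = _node(a.value ** p, [
        (a, lambda g: mul(g, mul(constant(p), power(a, p - 1.0)))),
    ])
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.value.ndim != 2 or b.value.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(a.value @ b.value, [
        (a, lambda g: matmul(g, transpose(b))),
        (b, lambda g: matmul(transpose(a), g)),
    ])


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    val = a.value.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            full = reshape(g, (1,) * a.value.ndim)
        elif not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.value.ndim for ax in axes)
            shp = tuple(1 if i in axes else s for i, s in enumerate(a.value.shape))
            full = reshape(g, shp)
        else:
            full = g
        return mul(full, constant(np.ones(a.value.shape)))

    return _node(val, [(a, backward)])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.value.shape
    return _node(a.value.reshape(shape), [(a, lambda g: reshape(g, old))])


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return _node(a.value.transpose(axes), [(a, lambda g: transpose(g, inv))])


def exp(a: Tensor) -> Tensor:
    out = _node(np.exp(a.value), [])
    if a.requires_grad:
        out = _node(out.value, [(a, lambda g: mul(g, out))])
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.value), [(a, lambda g: mul(g, power(a, -1.0)))])


def sqrt(a: Tensor) -> Tensor:
    out = _node(np.sqrt(a.value), [])
    if a.requires_grad:
        out = _node(out.value, [(a, lambda g: mul(g, mul(constant(0.5), power(out, -1.0))))])
    return out


def cos(a: Tensor) -> Tensor:
    return _node(np.cos(a.value), [(a, lambda g: mul(g, -sin(a)))])


def sin(a: Tensor) -> Tensor:
    return _node(np.sin(a.value), [(a, lambda g: mul(g, cos(a)))])


def sigmoid(a: Tensor) -> Tensor:
    val = 0.5 * (1.0 + np.tanh(0.5 * a.value))   # stable logistic
    out = _node(val, [])
    if a.requires_grad:
        out = _node(val, [(a, lambda g: mul(g, mul(out, add(constant(1.0), -out))))])
    return out


def softplus(a: Tensor) -> Tensor:
    """ln(1 + e^x), stabilized; derivative is the logistic function."""
    return _node(np.logaddexp(a.value, 0.0), [(a, lambda g: mul(g, sigmoid(a)))])


def take(a: Tensor, idx) -> Tensor:
    """Gather rows ``a[idx]`` along axis 0 (integer array indexing)."""
    idx = np.asarray(idx, dtype=np.intp)
    n = a.value.shape[0]
    return _node(a.value[idx], [(a, lambda g: scatter_add(g, idx, n))])


def scatter_add(a: Tensor, idx, n: int) -> Tensor:
    """out[idx[k]] += a[k] into zeros of leading size ``n``."""
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n,) + a.value.shape[1:])
    np.add.at(out, idx, a.value)
    return _node(out, [(a, lambda g: take(g, idx))])


def take2(a: Tensor, idx0, idx1) -> Tensor:
    """Gather ``a[idx0, idx1]`` for paired integer index arrays (2-D ``a``... or ND)."""
    idx0 = np.asarray(idx0, dtype=np.intp)
    idx1 = np.asarray(idx1, dtype=np.intp)
    shape = a.value.shape
    return _node(a.value[idx0, idx1], [(a, lambda g: scatter_add2(g, idx0, idx1, shape))])


def scatter_add2(a: Tensor, idx0, idx1, shape) -> Tensor:
    idx0 = np.asarray(idx0, dtype=np.intp)
    idx1 = np.asarray(idx1, dtype=np.intp)
    out = np.zeros(shape)
    np.add.at(out, (idx0, idx1), a.value)
    return _node(out, [(a, lambda g: take2(g, idx0, idx1))])


# -- gradient driver ----------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            stack.append((parent, False))
    return order          # parents before children


def grad(output: Tensor, inputs, grad_output=None):
    """Vector-Jacobian product of ``output`` w.r.t. each tensor in ``inputs``.

    Returns a list of Tensors (themselves differentiable).  Inputs that the
    output does not depend on receive a zero gradient of matching shape.
    """
    if grad_output is None:
        grad_output = constant(np.ones(output.value.shape))
    gmap = {id(output): grad_output}
    for node in reversed(_toposort(output)):
        g = gmap.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node.parents:
            if not parent.requires_grad:
                continue
            contrib = vjp(g)
            prev = gmap.get(id(parent))
            gmap[id(parent)] = contrib if prev is None else add(prev, contrib)
        gmap[id(node)] = g    # keep for inputs that are interior nodes
    return [gmap.get(id(t), constant(np.zeros(t.value.shape))) for t in inputs]
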