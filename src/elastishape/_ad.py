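"""Reverse-mode automatic differentiation on numpy arrays.

The discrete Sobolev path energies and varifold fidelity terms used throughout
this package are minimized with quasi-Newton methods, which need exact
gradients with respect to mesh vertex positions (and, for partial matching,
per-face weights).  The geodesic initial value problem additionally needs the
derivative of the metric with respect to its base surface — i.e. the gradient
of a gradient.  This module provides the small operator set required for those
energies, with every vector-Jacobian product itself expressed through the same
operators, so that ``grad(..., create_graph=True)`` yields a differentiable
expression and second-order quantities come out exact.

Design notes
------------
* :class:`Var` wraps a float64 ndarray plus references to its parents.  A
  computation involving at least one ``Var`` produces a ``Var``; pure-ndarray
  inputs short-circuit to plain numpy, so the same energy code serves both
  fast evaluation and gradient construction.
* Gradients are accumulated in topological order (iterative DFS — energy
  graphs can be deep).
* Only the primitives actually used by the package are implemented; this is
  not a general-purpose tensor library.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var", "var", "value", "is_var", "grad",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "sqrt", "absolute",
    "sum_", "reshape", "swapaxes", "matmul", "take", "scatter_add",
    "getitem", "concatenate", "stack", "where", "clip", "maximum",
    "rowdot", "cross3", "dot",
]


class Var:
    """A node in the computation graph: a value and its provenance."""

    __slots__ = ("value", "_parents")

    def __init__(self, value, parents=()):
        self.value = np.asarray(value, dtype=np.float64)
        self._parents = parents  # tuple of (Var, vjp) pairs

    # -- numpy-ish conveniences ------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape})"

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def var(x):
    """Create a leaf variable."""
    return Var(x)


def is_var(x):
    return isinstance(x, Var)


def value(x):
    """Underlying ndarray of a Var, or the input coerced to float64."""
    if isinstance(x, Var):
        return x.value
    return np.asarray(x, dtype=np.float64)


def _shape(x):
    return x.shape if isinstance(x, Var) else np.shape(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` (inverse of numpy broadcasting)."""
    gshape = _shape(g)
    if gshape == tuple(shape):
        return g
    # sum away prepended axes
    extra = len(gshape) - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
        gshape = _shape(g)
    axes = tuple(i for i, (a, b) in enumerate(zip(gshape, shape)) if b == 1 and a != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive constructors


def _make(values_fn, vjps):
    """Not used: ops are written explicitly for clarity/perf."""


def add(a, b):
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.add(a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, sa=av.shape: _unbroadcast(g, sa)))
    if isinstance(b, Var):
        parents.append((b, lambda g, sb=bv.shape: _unbroadcast(g, sb)))
    return Var(av + bv, tuple(parents))


def sub(a, b):
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.subtract(a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, sa=av.shape: _unbroadcast(g, sa)))
    if isinstance(b, Var):
        parents.append((b, lambda g, sb=bv.shape: _unbroadcast(neg(g), sb)))
    return Var(av - bv, tuple(parents))


def neg(a):
    if not isinstance(a, Var):
        return np.negative(a)
    return Var(-a.value, ((a, lambda g: neg(g)),))


def mul(a, b):
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.multiply(a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, b=b, sa=av.shape: _unbroadcast(mul(g, b), sa)))
    if isinstance(b, Var):
        parents.append((b, lambda g, a=a, sb=bv.shape: _unbroadcast(mul(g, a), sb)))
    return Var(av * bv, tuple(parents))


def div(a, b):
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.divide(a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, b=b, sa=av.shape: _unbroadcast(div(g, b), sa)))
    if isinstance(b, Var):
        parents.append(
            (b, lambda g, a=a, b=b, sb=bv.shape: _unbroadcast(
                neg(div(mul(g, a), mul(b, b))), sb))
        )
    return Var(av / bv, tuple(parents))


def pow_(a, p):
    """Elementwise power with a *constant* scalar exponent."""
    if not isinstance(a, Var):
        return np.power(a, p)
    out = Var(np.power(a.value, p))
    out._parents = ((a, lambda g, a=a, p=p: mul(g, mul(p, pow_(a, p - 1)))),)
    return out


def exp(a):
    if not isinstance(a, Var):
        return np.exp(a)
    out = Var(np.exp(a.value))
    out._parents = ((a, lambda g, out=out: mul(g, out)),)
    return out


def sqrt(a):
    if not isinstance(a, Var):
        return np.sqrt(a)
    out = Var(np.sqrt(a.value))
    out._parents = ((a, lambda g, out=out: div(g, mul(2.0, out))),)
    return out


def absolute(a):
    if not isinstance(a, Var):
        return np.abs(a)
    s = np.sign(a.value)
    return Var(np.abs(a.value), ((a, lambda g, s=s: mul(g, s)),))


def sum_(a, axis=None, keepdims=False):
    if not isinstance(a, Var):
        return np.sum(a, axis=axis, keepdims=keepdims)
    out_val = np.sum(a.value, axis=axis, keepdims=keepdims)
    ashape = a.value.shape

    def vjp(g, a=a, axis=axis, keepdims=keepdims, ashape=ashape):
        if axis is None:
            return mul(g, np.ones(ashape))
        ax = axis if isinstance(axis, tuple) else (axis,)
        ax = tuple(i % len(ashape) for i in ax)
        if not keepdims:
            kshape = tuple(1 if i in ax else s for i, s in enumerate(ashape))
            g = reshape(g, kshape)
        return mul(g, np.ones(ashape))

    return Var(out_val, ((a, vjp),))


def reshape(a, shape):
    if not isinstance(a, Var):
        return np.reshape(a, shape)
    ashape = a.value.shape
    return Var(np.reshape(a.value, shape), ((a, lambda g, s=ashape: reshape(g, s)),))


def swapaxes(a, i, j):
    if not isinstance(a, Var):
        return np.swapaxes(a, i, j)
    return Var(np.swapaxes(a.value, i, j), ((a, lambda g, i=i, j=j: swapaxes(g, i, j)),))


def matmul(a, b):
    """Matrix product; 2-D operands (or stacked with identical batch dims)."""
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.matmul(a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, b=b: matmul(g, swapaxes(b, -1, -2))))
    if isinstance(b, Var):
        parents.append((b, lambda g, a=a: matmul(swapaxes(a, -1, -2), g)))
    return Var(np.matmul(av, bv), tuple(parents))


def take(a, idx, axis=0):
    """Gather along ``axis`` with an integer index array."""
    if not isinstance(a, Var):
        return np.take(a, idx, axis=axis)
    n = a.value.shape[axis]
    out = np.take(a.value, idx, axis=axis)
    return Var(out, ((a, lambda g, idx=idx, n=n, axis=axis: scatter_add(g, idx, n, axis=axis)),))


def scatter_add(src, idx, n, axis=0):
    """Sum rows of ``src`` into a zero array with ``n`` slots along ``axis``.

    Inverse (adjoint) of :func:`take`; duplicate indices accumulate.
    """
    if not isinstance(src, Var):
        src = np.asarray(src, dtype=np.float64)
        shape = list(src.shape)
        shape[axis] = n
        out = np.zeros(shape)
        np.add.at(out, (slice(None),) * axis + (idx,), src)
        return out
    out_val = scatter_add(src.value, idx, n, axis=axis)
    return Var(out_val, ((src, lambda g, idx=idx, axis=axis: take(g, idx, axis=axis)),))


def getitem(a, key):
    if not isinstance(a, Var):
        return np.asarray(a)[key]
    ashape = a.value.shape
    return Var(a.value[key], ((a, lambda g, key=key, s=ashape: _scatter_slice(g, key, s)),))


def _scatter_slice(g, key, shape):
    """Adjoint of basic-slice ``getitem``: place ``g`` into zeros of ``shape``."""
    if not isinstance(g, Var):
        out = np.zeros(shape)
        out[key] = g
        return out
    out_val = np.zeros(shape)
    out_val[key] = g.value
    return Var(out_val, ((g, lambda gg, key=key: getitem(gg, key)),))


def concatenate(parts, axis=0):
    if not any(isinstance(p, Var) for p in parts):
        return np.concatenate(parts, axis=axis)
    vals = [value(p) for p in parts]
    out_val = np.concatenate(vals, axis=axis)
    parents = []
    offset = 0
    for p, v in zip(parts, vals):
        w = v.shape[axis]
        if isinstance(p, Var):
            key = (slice(None),) * (axis % out_val.ndim) + (slice(offset, offset + w),)
            parents.append((p, lambda g, key=key: getitem(g, key)))
        offset += w
    return Var(out_val, tuple(parents))


def stack(parts, axis=-1):
    nd = (value(parts[0]).ndim + 1)
    ax = axis % nd
    expanded = []
    for p in parts:
        s = list(_shape(p))
        s.insert(ax, 1)
        expanded.append(reshape(p, tuple(s)))
    return concatenate(expanded, axis=ax)


def where(cond, a, b):
    """Select with a *constant* boolean mask."""
    cond = np.asarray(cond, dtype=bool)
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.where(cond, a, b)
    av, bv = value(a), value(b)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g, c=cond, sa=av.shape: _unbroadcast(mul(g, c.astype(float)), sa)))
    if isinstance(b, Var):
        parents.append((b, lambda g, c=cond, sb=bv.shape: _unbroadcast(mul(g, (~c).astype(float)), sb)))
    return Var(np.where(cond, av, bv), tuple(parents))


def clip(a, lo, hi):
    """Clamp with constant bounds; gradient passes inside the active band."""
    if not isinstance(a, Var):
        return np.clip(a, lo, hi)
    mask = ((a.value >= lo) & (a.value <= hi)).astype(float)
    return Var(np.clip(a.value, lo, hi), ((a, lambda g, m=mask: mul(g, m)),))


def maximum(a, c):
    """Elementwise max against a constant."""
    if not isinstance(a, Var):
        return np.maximum(a, c)
    mask = (a.value >= c).astype(float)
    return Var(np.maximum(a.value, c), ((a, lambda g, m=mask: mul(g, m)),))


# ---------------------------------------------------------------------------
# composite helpers


def rowdot(a, b):
    """Row-wise dot product of (..., 3) arrays -> (...)."""
    return sum_(mul(a, b), axis=-1)


def dot(a, b):
    """Full contraction (sum of elementwise products)."""
    return sum_(mul(a, b))


def cross3(a, b):
    """Cross product of (..., 3) arrays, built from the primitive set."""
    if not (isinstance(a, Var) or isinstance(b, Var)):
        return np.cross(a, b)
    a0, a1, a2 = getitem(a, (..., 0)), getitem(a, (..., 1)), getitem(a, (..., 2))
    b0, b1, b2 = getitem(b, (..., 0)), getitem(b, (..., 1)), getitem(b, (..., 2))
    c0 = sub(mul(a1, b2), mul(a2, b1))
    c1 = sub(mul(a2, b0), mul(a0, b2))
    c2 = sub(mul(a0, b1), mul(a1, b0))
    return stack([c0, c1, c2], axis=-1)


# ---------------------------------------------------------------------------
# backward pass


def _toposort(root):
    order, seen = [], set()
    stack_ = [(root, False)]
    while stack_:
        node, done = stack_.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack_.append((parent, False))
    return order  # parents before children


def grad(output, inputs, create_graph=False):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients are themselves ``Var``
    nodes whose graph reaches back to the leaves, so they can be differentiated
    again (used by the discrete-geodesic stationarity residual).
    """
    if not isinstance(output, Var):
        raise TypeError("output must be a Var")
    if output.value.ndim != 0 and output.value.size != 1:
        raise ValueError("grad expects a scalar output")

    order = _toposort(output)
    grads: dict[int, object] = {id(output): np.ones_like(output.value)}
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node._parents:
            contrib = vjp(g)
            if not create_graph:
                contrib = value(contrib)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else add(prev, contrib)
            if not create_graph:
                grads[id(parent)] = value(grads[id(parent)])
        # keep leaf/input grads around
        if any(node is x for x in inputs):
            grads[id(node)] = g

    out = []
    for x in inputs:
        g = grads.get(id(x))
        if g is None:
            g = np.zeros_like(value(x))
            if create_graph:
                g = Var(g)
        out.append(g)
    return out
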