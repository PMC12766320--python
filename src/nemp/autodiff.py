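"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the primitives the potential
needs: elementwise math, broadcasting arithmetic, reductions, ``einsum``,
gather / scatter-add (for edge-to-node aggregation), slicing and
concatenation.  Every vector-Jacobian product is itself expressed in terms
of these primitives, so gradients are differentiable again — the engine
supports the mixed second derivatives required when a loss contains forces
(which are themselves first derivatives of the energy).

All data is kept in plain ``numpy`` arrays; no attempt is made at kernel
fusion.  The intended scale is desk-sized systems (thousands of edges),
where numpy's vectorised operations dominate the per-op Python overhead.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "tensor", "constant", "no_grad", "grad",
    "add", "sub", "mul", "div", "neg", "pow_", "exp", "log", "sin", "cos",
    "sqrt", "tanh", "sigmoid", "silu", "sum_", "reshape", "transpose",
    "broadcast_to", "getitem", "concat", "gather", "scatter_add", "einsum",
    "stack", "where_mask",
]

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


@contextlib.contextmanager
def default_dtype(dtype):
    """Run a block with a different working precision (e.g. float32 for
    training throughput); arrays passed into the tape are cast on entry."""
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (used for plain inference
    and for first-order-only backward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp: Callable | None = None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(
            data, dtype=_DEFAULT_DTYPE)
        rg = _GRAD_ENABLED and (requires_grad or any(p.requires_grad for p in parents))
        self.requires_grad = rg
        self._parents = parents if rg else ()
        self._vjp = vjp if rg else None

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(x, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(x, dtype=_DEFAULT_DTYPE), requires_grad=requires_grad)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=_DEFAULT_DTYPE))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


# ---------------------------------------------------------------------
# broadcasting helper: reduce a cotangent back to the operand's shape
# ---------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = sum_(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)
    return Tensor(a.data + b.data, parents=(a, b), vjp=vjp)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)
    return Tensor(a.data - b.data, parents=(a, b), vjp=vjp)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)
    return Tensor(a.data * b.data, parents=(a, b), vjp=vjp)


def div(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        ga = div(g, b)
        gb = neg(div(mul(g, a), mul(b, b)))
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)
    return Tensor(a.data / b.data, parents=(a, b), vjp=vjp)


def neg(a: Tensor) -> Tensor:
    def vjp(g):
        return (neg(g),)
    return Tensor(-a.data, parents=(a,), vjp=vjp)


def pow_(a: Tensor, p: float) -> Tensor:
    p = float(p)

    def vjp(g):
        return (mul(g, mul(constant(p), pow_(a, p - 1.0))),)
    return Tensor(a.data ** p, parents=(a,), vjp=vjp)


# NOTE: the vjp closures below recompute from the parent rather than
# capturing the output tensor — capturing it would make every graph node
# self-referential (node -> vjp -> node), turning whole tapes into cyclic
# garbage that only the generational collector can reclaim.

def exp(a: Tensor) -> Tensor:
    def vjp(g):
        return (mul(g, exp(a)),)
    return Tensor(np.exp(a.data), parents=(a,), vjp=vjp)


def log(a: Tensor) -> Tensor:
    def vjp(g):
        return (div(g, a),)
    return Tensor(np.log(a.data), parents=(a,), vjp=vjp)


def sin(a: Tensor) -> Tensor:
    def vjp(g):
        return (mul(g, cos(a)),)
    return Tensor(np.sin(a.data), parents=(a,), vjp=vjp)


def cos(a: Tensor) -> Tensor:
    def vjp(g):
        return (neg(mul(g, sin(a))),)
    return Tensor(np.cos(a.data), parents=(a,), vjp=vjp)


def sqrt(a: Tensor) -> Tensor:
    def vjp(g):
        return (div(mul(g, constant(0.5)), sqrt(a)),)
    return Tensor(np.sqrt(a.data), parents=(a,), vjp=vjp)


def tanh(a: Tensor) -> Tensor:
    def vjp(g):
        t = tanh(a)
        return (mul(g, sub(constant(1.0), mul(t, t))),)
    return Tensor(np.tanh(a.data), parents=(a,), vjp=vjp)


def sigmoid(a: Tensor) -> Tensor:
    def vjp(g):
        s = sigmoid(a)
        return (mul(g, mul(s, sub(constant(1.0), s))),)
    return Tensor(1.0 / (1.0 + np.exp(-a.data)), parents=(a,), vjp=vjp)


def silu(a: Tensor) -> Tensor:
    return mul(a, sigmoid(a))


# ---------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if isinstance(axis, int):
        axis = (axis,)

    def vjp(g):
        if axis is not None and not keepdims:
            shp = list(a.shape)
            for ax in axis:
                shp[ax % a.ndim] = 1
            g = reshape(g, tuple(shp))
        return (broadcast_to(g, a.shape),)
    return Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), parents=(a,), vjp=vjp)


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    def vjp(g):
        return (_unbroadcast(g, a.shape),)
    return Tensor(np.broadcast_to(a.data, shape).copy(), parents=(a,), vjp=vjp)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    def vjp(g):
        return (reshape(g, a.shape),)
    return Tensor(a.data.reshape(shape), parents=(a,), vjp=vjp)


def transpose(a: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)
    return Tensor(np.transpose(a.data, axes), parents=(a,), vjp=vjp)


def getitem(a: Tensor, idx) -> Tensor:
    """Basic (slice / integer / None-free) indexing."""
    def vjp(g):
        return (_scatter_slice(g, a.shape, idx),)
    return Tensor(a.data[idx], parents=(a,), vjp=vjp)


def _scatter_slice(g: Tensor, shape: tuple, idx) -> Tensor:
    def vjp(gg):
        return (getitem(gg, idx),)
    z = np.zeros(shape, dtype=g.data.dtype)
    z[idx] = g.data
    return Tensor(z, parents=(g,), vjp=vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for k, t in enumerate(tensors):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offs[k]), int(offs[k + 1]))
            outs.append(getitem(g, tuple(sl)))
        return tuple(outs)
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), vjp=vjp)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def vjp(g):
        outs = []
        for k in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = k
            outs.append(getitem(g, tuple(sl)))
        return tuple(outs)
    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), vjp=vjp)


# ---------------------------------------------------------------------
# gather / scatter (axis 0): the edge <-> node aggregation pair
# ---------------------------------------------------------------------

def gather(a: Tensor, indices: np.ndarray) -> Tensor:
    """``out[k] = a[indices[k]]`` along axis 0."""
    indices = np.asarray(indices, dtype=np.intp)
    n = a.shape[0]

    def vjp(g):
        return (scatter_add(g, indices, n),)
    return Tensor(a.data[indices], parents=(a,), vjp=vjp)


def scatter_add(a: Tensor, indices: np.ndarray, n: int) -> Tensor:
    """``out[i] = sum over k with indices[k] == i of a[k]`` (segment sum)."""
    indices = np.asarray(indices, dtype=np.intp)

    def vjp(g):
        return (gather(g, indices),)
    tail = int(np.prod(a.shape[1:], dtype=np.intp)) if a.ndim > 1 else 1
    if a.ndim > 1 and len(indices) * tail > 0:
        # bincount on a composite flat index: same accumulation order as a
        # sequential scatter, but far faster than np.add.at
        flat = (indices[:, None] * tail + np.arange(tail, dtype=np.intp)).ravel()
        z = np.bincount(flat, weights=a.data.ravel(),
                        minlength=n * tail).reshape((n,) + a.shape[1:])
        z = z.astype(a.data.dtype, copy=False)
    else:
        z = np.zeros((n,) + a.shape[1:], dtype=a.data.dtype)
        np.add.at(z, indices, a.data)
    return Tensor(z, parents=(a,), vjp=vjp)


# ---------------------------------------------------------------------
# einsum (two operands; every index of one operand must appear in the
# other operand or in the output — holds for all contractions used here)
# ---------------------------------------------------------------------

def einsum(spec: str, a: Tensor, b: Tensor, optimize: bool = True) -> Tensor:
    """Two-operand einsum.  ``optimize=False`` forces the non-BLAS kernel,
    whose row results are independent of row order (BLAS gemv is not) —
    used where bit-level permutation invariance matters."""
    a, b = _as_tensor(a), _as_tensor(b)
    ins, out_sub = spec.replace(" ", "").split("->")
    s1, s2 = ins.split(",")
    if len(set(s1)) != len(s1) or len(set(s2)) != len(s2):
        raise ValueError(f"repeated index within one operand: {spec!r}")
    for ch in s1:
        if ch not in s2 and ch not in out_sub:
            raise ValueError(f"index {ch!r} summed within a single operand: {spec!r}")
    for ch in s2:
        if ch not in s1 and ch not in out_sub:
            raise ValueError(f"index {ch!r} summed within a single operand: {spec!r}")

    def vjp(g):
        ga = einsum(f"{out_sub},{s2}->{s1}", g, b)
        gb = einsum(f"{s1},{out_sub}->{s2}", a, g)
        return ga, gb
    return Tensor(np.einsum(spec, a.data, b.data, optimize=optimize),
                  parents=(a, b), vjp=vjp)


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where a boolean constant mask holds, else ``b``."""
    a, b = _as_tensor(a), _as_tensor(b)
    mask = np.asarray(mask, dtype=bool)

    def vjp(g):
        zero = constant(0.0)
        return (where_mask(mask, g, zero), where_mask(~mask, g, zero))
    return Tensor(np.where(mask, a.data, b.data), parents=(a, b), vjp=vjp)


# ---------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------

def _topo(root: Tensor) -> list:
    order, seen, stack_ = [], set(), [(root, False)]
    while stack_:
        node, done = stack_.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack_.append((p, False))
    return order


def grad(output: Tensor, inputs: Sequence[Tensor], grad_output: Tensor | None = None,
         create_graph: bool = False) -> list[Tensor]:
    """Cotangents of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own tape
    and can be differentiated again (used for force-loss training).
    """
    if grad_output is None:
        grad_output = constant(np.ones_like(output.data))
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        order = _topo(output)
        cot: dict[int, Tensor] = {id(output): grad_output}
        for node in reversed(order):
            g = cot.get(id(node))
            if g is None or node._vjp is None:
                continue
            parts = node._vjp(g)
            for p, pg in zip(node._parents, parts):
                if pg is None or not p.requires_grad:
                    continue
                acc = cot.get(id(p))
                cot[id(p)] = pg if acc is None else add(acc, pg)
        res = []
        for t in inputs:
            g = cot.get(id(t))
            res.append(g if g is not None else constant(np.zeros_like(t.data)))
    return res
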