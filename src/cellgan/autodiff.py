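"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core behind the adversarial training code. It supports
the small set of operations an MLP critic/generator needs (affine maps, ReLU,
reductions, elementwise arithmetic) and — crucially — *differentiable*
vector-Jacobian products: the cotangents produced during backpropagation are
themselves graph nodes, so a second ``grad`` call differentiates through a
first one. That double-backpropagation is what the WGAN gradient penalty
requires (the critic loss contains the norm of a gradient).

Design notes
------------
* Everything is float64. The tensors here are tiny (desk-scale MLPs), so
  clarity and reproducibility beat throughput.
* ``grad(out, wrt)`` follows the sum-of-outputs convention when ``out`` is not
  scalar (seeded with ones), like ``torch.autograd.grad`` with an implicit
  ones cotangent.
* The ReLU derivative treats the subgradient at 0 as 0 and the 0/1 mask as a
  constant, the almost-everywhere-correct convention double backprop relies
  on.
* ``take_rows`` (the gather used by conditional batch normalization) has a
  first-order-only vjp: its scatter-add cotangent is emitted as a leaf. It is
  never on the gradient-penalty path, which only traverses the critic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "matmul",
    "transpose",
    "relu",
    "tsum",
    "tmean",
    "power",
    "reshape",
    "broadcast_to",
    "take_rows",
]


class Tensor:
    """A NumPy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "parents", "_vjp")

    def __init__(self, data, parents=(), vjp=None):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.parents = parents
        self._vjp = vjp

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, leaf={self._vjp is None})"

    # -- operator overloads ----------------------------------------------
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
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):  # pragma: no cover - defensive
        g = reshape(g, tuple(shape))
    return g


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(a.data + b.data, (a, b), vjp)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)

    return Tensor(a.data - b.data, (a, b), vjp)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return Tensor(a.data * b.data, (a, b), vjp)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = div(g, b)
        gb = neg(div(mul(g, a), mul(b, b)))
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor(a.data / b.data, (a, b), vjp)


def neg(a):
    a = as_tensor(a)

    def vjp(g):
        return (neg(g),)

    return Tensor(-a.data, (a,), vjp)


def power(a, p):
    """Elementwise ``a ** p`` for a *constant* float exponent."""
    a = as_tensor(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(p, power(a, p - 1.0))),)

    return Tensor(a.data ** p, (a,), vjp)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return Tensor(a.data @ b.data, (a, b), vjp)


def transpose(a):
    a = as_tensor(a)

    def vjp(g):
        return (transpose(g),)

    return Tensor(a.data.T, (a,), vjp)


def relu(a):
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))

    def vjp(g):
        return (mul(g, mask),)

    return Tensor(np.maximum(a.data, 0.0), (a,), vjp)


def reshape(a, shape):
    a = as_tensor(a)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return Tensor(a.data.reshape(shape), (a,), vjp)


def broadcast_to(a, shape):
    a = as_tensor(a)

    def vjp(g):
        return (_unbroadcast(g, a.shape),)

    return Tensor(np.broadcast_to(a.data, shape).copy(), (a,), vjp)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if axis is None:
            gd = reshape(gd, (1,) * a.ndim) if a.ndim else gd
        elif not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            kshape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gd = reshape(gd, kshape)
        return (broadcast_to(gd, a.shape),)

    return Tensor(np.asarray(out), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def take_rows(a, idx):
    """Row gather ``a[idx]``; first-order vjp only (scatter-add leaf)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        z = np.zeros_like(a.data)
        np.add.at(z, idx, g.data)
        return (Tensor(z),)

    return Tensor(a.data[idx], (a,), vjp)


# ---------------------------------------------------------------------------
# backpropagation
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, iter(root.parents))]
    seen.add(id(root))
    while stack:
        node, it = stack[-1]
        advanced = False
        for p in it:
            if id(p) not in seen:
                seen.add(id(p))
                stack.append((p, iter(p.parents)))
                advanced = True
                break
        if not advanced:
            order.append(node)
            stack.pop()
    return order  # parents before children


def grad(out: Tensor, wrt, create_graph: bool = False):
    """Gradients of ``out`` (summed if non-scalar) w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned tensors carry their own history so
    a further ``grad`` through them is valid (used for the gradient penalty).
    """
    order = _toposort(out)
    cotangents: dict[int, Tensor] = {id(out): Tensor(np.ones_like(out.data))}
    for node in reversed(order):
        g = cotangents.get(id(node))
        if g is None or node._vjp is None:
            continue
        for parent, pg in zip(node.parents, node._vjp(g)):
            if pg is None:
                continue
            cur = cotangents.get(id(parent))
            cotangents[id(parent)] = pg if cur is None else add(cur, pg)
    results = []
    for w in wrt:
        g = cotangents.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        elif g.shape != w.shape:  # broadcasting of a leaf used as scalar
            g = _unbroadcast(g, w.shape)
        if not create_graph:
            g = Tensor(g.data.copy())
        results.append(g)
    return results
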