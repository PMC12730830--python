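"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the primitives the graph networks
need: broadcast arithmetic, matrix products, batched products against a
constant operand, row gather / scatter-add (message passing), elementwise
nonlinearities, reductions and reshapes.  Everything runs in float64;
gradients are accumulated by a topological backward sweep.  Correctness is
established against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t.grad_fn is not None:
                t.grad_fn(t.grad)
                t.grad = None  # free activation gradients; leaves keep theirs

    def _accumulate(self, grad):
        # backward closures never mutate incoming gradients, so the first
        # contribution can be stored by reference (out-of-place add later)
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def _unary(x: Tensor, out_data: np.ndarray, local_grad) -> Tensor:
    out = Tensor(out_data, parents=(x,))

    def fn(g):
        x._accumulate(local_grad(g))

    out.grad_fn = fn if out.requires_grad else None
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def fn(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out.grad_fn = fn if out.requires_grad else None
    return out


def neg(x: Tensor) -> Tensor:
    return _unary(x, -x.data, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def fn(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out.grad_fn = fn if out.requires_grad else None
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def fn(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out.grad_fn = fn if out.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a (..., m, k) @ b (k, n); b must be 2-D (a weight matrix)."""
    if b.data.ndim != 2:
        raise ValueError("matmul right operand must be 2-D")
    out = Tensor(a.data @ b.data, parents=(a, b))

    def fn(g):
        a._accumulate(g @ b.data.T)
        lead = tuple(range(g.ndim - 1))
        b._accumulate(np.tensordot(a.data, g, axes=(lead, lead)))

    out.grad_fn = fn if out.requires_grad else None
    return out


def bmm_const(A: np.ndarray, x: Tensor) -> Tensor:
    """Batched product A @ x with a constant left operand A (B, m, k)."""
    out = Tensor(A @ x.data, parents=(x,))

    def fn(g):
        x._accumulate(np.swapaxes(A, -1, -2) @ g)

    out.grad_fn = fn if out.requires_grad else None
    return out


def relu(x: Tensor) -> Tensor:
    m = x.data > 0  # boolean mask: 8x lighter than a float multiplier
    return _unary(x, np.where(m, x.data, 0.0), lambda g: np.where(m, g, 0.0))


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    m = x.data > 0
    return _unary(x, np.where(m, x.data, alpha * x.data),
                  lambda g: np.where(m, g, alpha * g))


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    e = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    pos = x.data > 0
    out_data = np.where(pos, x.data, e)
    return _unary(x, out_data, lambda g: g * np.where(pos, 1.0, e + alpha))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, s, lambda g: g * s * (1.0 - s))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return _unary(x, e, lambda g: g * e)


def softplus(x: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, out_data, lambda g: g * s)


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def local(g):
        if axis is None:
            return np.broadcast_to(g, x.data.shape).copy()
        gg = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(gg, x.data.shape).copy()

    return _unary(x, out_data, local)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(x: Tensor, shape) -> Tensor:
    return _unary(x, x.data.reshape(shape), lambda g: g.reshape(x.data.shape))


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Rows x[idx] along axis 0."""
    out = Tensor(x.data[idx], parents=(x,))

    def fn(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    out.grad_fn = fn if out.requires_grad else None
    return out


def scatter_add(x: Tensor, idx: np.ndarray, size: int) -> Tensor:
    """out[n] = sum of x[e] over entries e with idx[e] == n (axis 0)."""
    out_data = np.zeros((size,) + x.data.shape[1:])
    np.add.at(out_data, idx, x.data)
    out = Tensor(out_data, parents=(x,))

    def fn(g):
        x._accumulate(g[idx])

    out.grad_fn = fn if out.requires_grad else None
    return out


def attn_score(m: Tensor, att: Tensor, alpha: float = 0.2) -> Tensor:
    """Fused GATv2 attention logit: sum_o att[h,o] * leaky_relu(m[e,h,o]).

    Streams over the large per-edge tensor without materializing the
    activated copy or the elementwise product (einsum), storing only a
    boolean sign mask for the backward pass.
    """
    pos = m.data > 0
    act = np.where(pos, m.data, alpha * m.data)
    out = Tensor(np.einsum("eho,ho->eh", act, att.data[0]), parents=(m, att))

    def fn(g):
        slope = np.where(pos, 1.0, alpha)
        m._accumulate(g[:, :, None] * att.data[0] * slope)
        a_grad = np.einsum("eho,eh->ho", np.where(pos, m.data, alpha * m.data), g)
        att._accumulate(a_grad[None, :, :])

    out.grad_fn = fn if out.requires_grad else None
    return out


def sparse_matmul_const(A, AT, x: Tensor) -> Tensor:
    """out = A @ x for a constant sparse operator A (rows select/accumulate).

    ``AT`` must be A transposed (precomputed CSR) so the backward pass is a
    single sparse product; trailing axes of x are flattened for the product
    and restored afterwards.  Used for edge gather (A row-selects node rows)
    and segment scatter-add (A accumulates edge rows per node), which are an
    order of magnitude faster as CSR products than fancy-index accumulation.
    """
    shape = x.data.shape
    x2 = x.data.reshape(shape[0], -1)
    out2 = A @ x2
    out = Tensor(out2.reshape((A.shape[0],) + shape[1:]), parents=(x,))

    def fn(g):
        g2 = g.reshape(A.shape[0], -1)
        x._accumulate((AT @ g2).reshape(shape))

    out.grad_fn = fn if out.requires_grad else None
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def fn(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out.grad_fn = fn if out.requires_grad else None
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(mask))
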