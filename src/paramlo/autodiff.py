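"""Minimal reverse-mode automatic differentiation with higher-order support.

The meta-learning machinery in this package needs gradients *of* gradients:
the outer objective differentiates through one-step gradient updates of two
inner models.  Every primitive therefore expresses its vector-Jacobian
product (VJP) in terms of the same traced primitives, so a gradient returned
by :func:`grad` with ``create_graph=True`` is itself a differentiable graph.

All arithmetic is float64.  The engine is deliberately small: only the
operations the reference models use are provided.  Tensors are immutable
once created; parameters are leaves with ``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "constant",
    "grad",
    "add",
    "mul",
    "div",
    "neg",
    "pow_const",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "relu",
    "matmul",
    "transpose",
    "reshape",
    "tsum",
    "tmean",
    "broadcast_to",
    "concat",
    "stack",
    "getitem",
    "gather_rows",
    "take_rowwise",
    "softmax",
    "log_softmax",
    "dropout",
    "norm2",
    "numerical_gradient",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _vjps: tuple = (),
    ):
        a = np.asarray(data, dtype=np.float64)
        self.data = a
        self.requires_grad = requires_grad
        self._parents = _parents
        self._vjps = _vjps

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        flag = ", grad" if (self.requires_grad or self._parents) else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __neg__(self):
        return neg(self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return pow_const(self, float(p))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def constant(data) -> Tensor:
    return Tensor(data)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjps) -> Tensor:
    return Tensor(data, _parents=tuple(parents), _vjps=tuple(vjps))


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a gradient back to the shape of its operand
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.data.shape == shape:
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data + b.data,
        (a, b),
        (
            lambda g: _unbroadcast(g, a.data.shape),
            lambda g: _unbroadcast(g, b.data.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data * b.data,
        (a, b),
        (
            lambda g: _unbroadcast(mul(g, b), a.data.shape),
            lambda g: _unbroadcast(mul(g, a), b.data.shape),
        ),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data / b.data,
        (a, b),
        (
            lambda g: _unbroadcast(div(g, b), a.data.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape),
        ),
    )


def pow_const(a: Tensor, p: float) -> Tensor:
    def vjp(g):
        return mul(g, mul(Tensor(np.float64(p)), pow_const(a, p - 1.0)))

    return _make(a.data**p, (a,), (vjp,))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), ())
    out._vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), (lambda g: div(g, a),))


def tanh(a: Tensor) -> Tensor:
    out = _make(np.tanh(a.data), (a,), ())
    out._vjps = (lambda g: mul(g, add(Tensor(1.0), neg(mul(out, out)))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)
    out = _make(out_data, (a,), ())
    out._vjps = (lambda g: mul(g, mul(out, add(Tensor(1.0), neg(out)))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return _make(a.data * mask.data, (a,), (lambda g: mul(g, mask),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data @ b.data,
        (a, b),
        (
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


def transpose(a: Tensor, axes=None) -> Tensor:
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return _make(
        np.transpose(a.data, axes), (a,), (lambda g: transpose(g, inv),)
    )


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    return _make(a.data.reshape(shape), (a,), (lambda g: reshape(g, orig),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    return _make(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        (lambda g: _unbroadcast(g, orig),),
    )


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    orig = a.data.shape

    if axis is None:
        ax = tuple(range(a.data.ndim))
    elif isinstance(axis, int):
        ax = (axis % a.data.ndim,)
    else:
        ax = tuple(i % a.data.ndim for i in axis)

    def vjp(g):
        if not keepdims:
            kd_shape = tuple(
                1 if i in ax else s for i, s in enumerate(orig)
            )
            g = reshape(g, kd_shape)
        return broadcast_to(g, orig)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), (vjp,))


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    elif isinstance(axis, int):
        n = a.data.shape[axis]
    else:
        n = int(np.prod([a.data.shape[i] for i in axis]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    datas = [t.data for t in tensors]
    ax = axis % datas[0].ndim
    sizes = [d.shape[ax] for d in datas]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    vjps = []
    for k in range(len(tensors)):
        idx = tuple(
            slice(int(offsets[k]), int(offsets[k + 1])) if i == ax else slice(None)
            for i in range(datas[0].ndim)
        )
        vjps.append(lambda g, idx=idx: getitem(g, idx))

    return _make(np.concatenate(datas, axis=axis), tensors, vjps)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shp = list(t.data.shape)
        shp.insert(axis % (t.data.ndim + 1), 1)
        expanded.append(reshape(t, tuple(shp)))
    return concat(expanded, axis=axis)


def getitem(a: Tensor, idx) -> Tensor:
    orig = a.data.shape
    return _make(
        a.data[idx], (a,), (lambda g: _slice_adjoint(g, orig, idx),)
    )


def _slice_adjoint(g: Tensor, shape, idx) -> Tensor:
    out = np.zeros(shape, dtype=np.float64)
    out[idx] = g.data  # basic slicing selects each element at most once
    return _make(out, (g,), (lambda gg: getitem(gg, idx),))


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """a[idx] along axis 0, idx an integer array (repeats allowed)."""
    idx = np.asarray(idx)
    orig = a.data.shape
    return _make(
        a.data[idx], (a,), (lambda g: _scatter_rows(g, idx, orig),)
    )


def _scatter_rows(g: Tensor, idx: np.ndarray, shape) -> Tensor:
    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return _make(out, (g,), (lambda gg: gather_rows(gg, idx),))


def take_rowwise(a: Tensor, col_idx: np.ndarray) -> Tensor:
    """a[i, col_idx[i]] for a 2-D tensor; returns a vector of length n."""
    col_idx = np.asarray(col_idx)
    n = a.data.shape[0]
    rows = np.arange(n)
    orig = a.data.shape
    return _make(
        a.data[rows, col_idx],
        (a,),
        (lambda g: _scatter_rowwise(g, col_idx, orig),),
    )


def _scatter_rowwise(g: Tensor, col_idx: np.ndarray, shape) -> Tensor:
    out = np.zeros(shape, dtype=np.float64)
    rows = np.arange(shape[0])
    np.add.at(out, (rows, col_idx), g.data)
    return _make(out, (g,), (lambda gg: take_rowwise(gg, col_idx),))


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    c = Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(a - c)
    return div(e, tsum(e, axis=axis, keepdims=True))


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    c = Tensor(np.max(a.data, axis=axis, keepdims=True))
    s = a - c
    return s - log(tsum(exp(s), axis=axis, keepdims=True))


def dropout(a: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate == 0.0:
        return a
    keep = 1.0 - rate
    mask = Tensor((rng.random(a.data.shape) < keep).astype(np.float64) / keep)
    return mul(a, mask)


def norm2(a: Tensor) -> Tensor:
    return pow_const(tsum(mul(a, a)), 0.5)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def _topo_order(output: Tensor) -> list:
    order: list = []
    seen: set = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # parents precede children


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors are themselves nodes of
    a differentiable graph, enabling second (and higher) derivatives.
    Inputs not connected to the output receive zero gradients.
    """
    inputs = list(inputs)
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")

    order = _topo_order(output)
    relevant = {id(t) for t in inputs}
    for node in order:
        if id(node) in relevant:
            continue
        for p in node._parents:
            if id(p) in relevant:
                relevant.add(id(node))
                break

    grads: dict = {}
    if id(output) in relevant:
        grads[id(output)] = Tensor(np.ones_like(output.data))

    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for p, vjp in zip(node._parents, node._vjps):
            if id(p) not in relevant:
                continue
            pg = vjp(g)
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)
        # keep gradients of requested leaves around
        if node in inputs:
            grads[id(node)] = g

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# testing utility
# ---------------------------------------------------------------------------


def numerical_gradient(
    f: Callable[[], Tensor], leaf: Tensor, eps: float = 1e-6
) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. ``leaf.data``."""
    base = leaf.data.copy()
    out = np.zeros_like(base)
    it = np.nditer(base, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        leaf.data = base.copy()
        leaf.data[i] = base[i] + eps
        hi = f().item()
        leaf.data = base.copy()
        leaf.data[i] = base[i] - eps
        lo = f().item()
        out[i] = (hi - lo) / (2 * eps)
        it.iternext()
    leaf.data = base
    return out
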