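"""Minimal reverse-mode automatic differentiation on numpy arrays.

The community structure module is small (a few million parameters at full
size, tens of thousands at toy size) and runs on CPU, so a lean tape-based
engine over numpy is sufficient: every op records its parents and a closure
that maps the upstream gradient to parent gradients; ``Tensor.backward``
walks the tape in reverse topological order.

Only the ops the model actually uses are implemented.  Broadcasting is
supported through :func:`_unbroadcast`.
"""

from __future__ import annotations

import contextlib
import gc

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "einsum", "matmul",
           "graph_context"]


@contextlib.contextmanager
def graph_context():
    """Disable the cyclic garbage collector while building/backpropagating a
    graph.  The tape is acyclic, so reference counting reclaims it; leaving
    the GC on makes generation-2 scans quadratic in graph size."""
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bwd", "requires_grad", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), bwd=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._bwd = bwd
        self.name = name

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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- graph plumbing ------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack_ = [(self, False)]
        while stack_:
            node, done = stack_.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited or not (node.requires_grad or node._parents):
                continue
            visited.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._bwd is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._bwd(g)):
                if pg is None:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        del grads

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out._parents:
            out._bwd = lambda g: (_unbroadcast(g, self.shape),
                                  _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        out = _make(self.data - other.data, (self, other))
        if out._parents:
            out._bwd = lambda g: (_unbroadcast(g, self.shape),
                                  _unbroadcast(-g, other.shape))
        return out

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out._parents:
            out._bwd = lambda g: (-g,)
        return out

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out._parents:
            out._bwd = lambda g: (_unbroadcast(g * other.data, self.shape),
                                  _unbroadcast(g * self.data, other.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out._parents:
            out._bwd = lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out._parents:
            out._bwd = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- elementwise functions ----------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._bwd = lambda g: (g * y,)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._bwd = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._bwd = lambda g: (g * 0.5 / y,)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out._parents:
            out._bwd = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(y, (self,))
        if out._parents:
            out._bwd = lambda g: (g * y * (1.0 - y),)
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out._parents:
            out._bwd = lambda g: (g * mask,)
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo
        out = _make(np.maximum(self.data, lo), (self,))
        if out._parents:
            out._bwd = lambda g: (g * mask,)
        return out

    def clip_max(self, hi: float):
        mask = self.data < hi
        out = _make(np.minimum(self.data, hi), (self,))
        if out._parents:
            out._bwd = lambda g: (g * mask,)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            shape = self.shape

            def bwd(g):
                if axis is None:
                    return (np.broadcast_to(g, shape).copy(),)
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % len(shape) for a in axes):
                        gg = np.expand_dims(gg, ax)
                return (np.broadcast_to(gg, shape).copy(),)

            out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._bwd = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            out._bwd = lambda g: (g.transpose(inv),)
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bwd(g):
                full = np.zeros(self.shape)
                np.add.at(full, idx, g)
                return (full,)
            out._bwd = bwd
        return out

    # -- composites ----------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def _make(data, parents):
    req = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=parents if req else (), name=None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out._parents:
        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        out._bwd = bwd
    return out


def einsum(subscripts: str, *ops: Tensor) -> Tensor:
    """Differentiable einsum (no ellipsis, no repeated in-operand indices)."""
    ops = tuple(as_tensor(o) for o in ops)
    ins, outs = subscripts.split("->")
    in_subs = ins.split(",")
    out = _make(np.einsum(subscripts, *[o.data for o in ops], optimize=True),
                ops)
    if out._parents:
        def bwd(g):
            grads = []
            for i, sub in enumerate(in_subs):
                other_subs = [outs] + [s for j, s in enumerate(in_subs) if j != i]
                other_ops = [g] + [o.data for j, o in enumerate(ops) if j != i]
                spec = ",".join(other_subs) + "->" + sub
                grads.append(np.einsum(spec, *other_ops, optimize=True))
            return grads
        out._bwd = bwd
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._bwd = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        out._bwd = lambda g: tuple(np.moveaxis(g, axis, 0))
    return out
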