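"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ``ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op set is deliberately small — exactly what the
dual-branch network needs: broadcasting arithmetic, batched ``matmul``,
reductions, reshaping, concatenation, elementwise nonlinearities, and the
``softmax`` / ``layer_norm`` compounds built from them.

All data is kept in double precision; gradients broadcast back to the shape
of their source via :func:`_unbroadcast`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "layer_norm", "silu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- graph construction --------------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, n: float):
        a = self

        def backward(g):
            a._accumulate(g * n * a.data ** (n - 1))

        return Tensor._node(a.data ** n, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires >=2-D operands")

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._node(a.data @ b.data, (a, b), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not keepdims and axis is not None:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor._node(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(np.transpose(g, inv))

        return Tensor._node(np.transpose(a.data, axes), (a,), backward)

    # -- nonlinearities ------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._node(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._node(np.log(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._node(s, (a,), backward)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - t * t))

        return Tensor._node(t, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._node(a.data * mask, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient flows only through unclipped entries."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._node(np.clip(a.data, lo, hi), (a,), backward)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, int]] = [(self, 0)]
        visited.add(id(self))
        while stack:
            node, idx = stack.pop()
            parents = [p for p in node._parents if p.requires_grad]
            if idx < len(parents):
                stack.append((node, idx + 1))
                child = parents[idx]
                if id(child) not in visited:
                    visited.add(id(child))
                    stack.append((child, 0))
            else:
                topo.append(node)
        # reset non-leaf gradients so repeated backward passes over a shared
        # graph (e.g. one pass per task) do not mix; leaves keep accumulating
        for node in topo:
            if node._backward is not None:
                node.grad = None
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- free functions ----------------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._node(data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._coerce(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else len(shape) + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x.data.max(axis=axis, keepdims=True)  # constant: detached shift
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def silu(x: Tensor) -> Tensor:
    return x * x.sigmoid()


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias
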