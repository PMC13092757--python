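"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the model needs: dense matmul,
broadcasting add/mul, elementwise nonlinearities, row gathering,
concatenation, reductions and a masked row-softmax. Tensors form a DAG;
``Tensor.backward()`` runs a topological sweep accumulating gradients
into every node with ``requires_grad``.

Shapes are plain numpy shapes; float64 throughout, which keeps
finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack_mean"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
        """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcast)."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g, other.shape))

        return Tensor(out_data, req, (self, other), bwd if req else None)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(self._unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(self._unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, req, (self, other), bwd if req else None)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.pow(-1.0)
        return self * (1.0 / other)

    def pow(self, exponent: float):
        out_data = self.data ** exponent
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, req, (self,), bwd if req else None)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data
        req = self.requires_grad or other.requires_grad

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, req, (self, other), bwd if req else None)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, req, (self,), bwd if req else None)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor(out_data, req, (self,), bwd if req else None)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, req, (self,), bwd if req else None)

    def log(self):
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), req, (self,), bwd if req else None)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, req, (self,), bwd if req else None)

    # -- shape ops ---------------------------------------------------------

    def transpose(self):
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, req, (self,), bwd if req else None)

    def gather_rows(self, index):
        """Select rows by integer index (with repetition allowed)."""
        index = np.asarray(index, dtype=np.intp)
        req = self.requires_grad

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accumulate(acc)

        return Tensor(self.data[index], req, (self,), bwd if req else None)

    def reshape(self, *shape):
        orig = self.shape
        req = self.requires_grad

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), req, (self,), bwd if req else None)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        req = self.requires_grad

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, req, (self,), bwd if req else None)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def std(self, axis=0, eps: float = 1e-12):
        """Per-axis standard deviation (population, ddof=0), differentiable."""
        mu = self.mean(axis=axis, keepdims=True)
        var = ((self - mu).pow(2.0)).mean(axis=axis)
        return (var + eps).sqrt()

    def masked_row_softmax(self, mask: np.ndarray):
        """Softmax over axis=1 restricted to ``mask`` (boolean, same shape).

        Rows with no unmasked entry yield all-zero rows.
        """
        neg = np.where(mask, self.data, -np.inf)
        m = np.max(neg, axis=1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.where(mask, np.exp(neg - m), 0.0)
        denom = e.sum(axis=1, keepdims=True)
        denom = np.where(denom == 0.0, 1.0, denom)
        out_data = e / denom
        req = self.requires_grad

        def bwd(g):
            # d softmax: s * (g - sum(g*s))
            dot = (g * out_data).sum(axis=1, keepdims=True)
            self._accumulate(np.where(mask, out_data * (g - dot), 0.0))

        return Tensor(out_data, req, (self,), bwd if req else None)


class Parameter(Tensor):
    """A leaf tensor that optimizers update."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 1) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)

    def bwd(g):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, req, tuple(tensors), bwd if req else None)


def stack_mean(tensors) -> Tensor:
    """Mean of a list of same-shape tensors (layer-state aggregation)."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out * (1.0 / len(tensors))
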