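"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine exists so the recurrent fusion models and the path-integral
gradient attributions share one differentiable computation graph. It is a
tape-based design: every operation appends a node holding its inputs and a
backward closure; :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients. Only the operations the package
needs are implemented (dense algebra, gated recurrences, embedding gathers,
pooling, sigmoid/BCE heads), all vectorised over a batch axis.

Gradients flow to *inputs* as well as parameters, which is what integrated
gradients requires: mark any Tensor with ``requires_grad=True`` and read
``.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack", "sigmoid", "tanh", "sin", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (recurrences make graphs deep)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None or not node._parents:
                # leaf (parameter or input): accumulate into .grad
                node.grad = g.copy() if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        return self._make(self.data + other.data, (self, other), lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = self._lift(other)
        return self._make(self.data - other.data, (self, other), lambda g: (g, -g))

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        other = self._lift(other)
        return self._make(
            self.data * other.data,
            (self, other),
            lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self._make(
            self.data / other.data,
            (self, other),
            lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __rtruediv__(self, other):
        return self._lift(other).__truediv__(self)

    def __pow__(self, exponent: float):
        e = float(exponent)
        return self._make(
            self.data**e, (self,), lambda g: (g * e * self.data ** (e - 1),)
        )

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def back(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ga, gb

        return self._make(self.data @ other.data, (self, other), back)

    __matmul__ = matmul

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def __getitem__(self, idx):
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(Ellipsis))) for p in parts)

        def back(g):
            out = np.zeros_like(self.data)
            if basic:  # non-overlapping selection: plain assignment suffices
                out[idx] += g
            else:
                np.add.at(out, idx, g)
            return (out,)

        return self._make(self.data[idx], (self,), back)

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)

        def back(g):
            out = np.zeros_like(self.data)
            g2 = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(
                out, np.expand_dims(idx, axis), g2, axis=axis
            )
            return (out,)

        val = np.max(self.data, axis=axis, keepdims=keepdims)
        return self._make(val, (self,), back)

    def gather_rows(self, indices: np.ndarray) -> "Tensor":
        """Embedding lookup: rows of a (V, E) matrix at integer `indices`."""
        indices = np.asarray(indices)

        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, indices.ravel(), g.reshape(-1, self.data.shape[1]))
            return (out,)

        return self._make(self.data[indices], (self,), back)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return self._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out = np.tanh(self.data)
        return self._make(out, (self,), lambda g: (g * (1.0 - out**2),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def sin(self):
        return self._make(np.sin(self.data), (self,), lambda g: (g * np.cos(self.data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = back
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    return Tensor._lift(x).sigmoid()


def tanh(x: Tensor) -> Tensor:
    return Tensor._lift(x).tanh()


def sin(x: Tensor) -> Tensor:
    return Tensor._lift(x).sin()


def relu(x: Tensor) -> Tensor:
    return Tensor._lift(x).relu()


class Adam:
    """Adaptive-moment first-order optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
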