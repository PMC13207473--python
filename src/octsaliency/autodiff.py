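"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set needed by the windowed-attention
classifier and its capture contract: broadcast arithmetic, batched matmul,
shape manipulation (reshape/transpose/cyclic roll), softmax / log-softmax,
layer normalisation, GELU/ReLU, reductions and gathers.  Gradients are
accumulated on every tensor that participates in the graph, so intermediate
arrays (attention probabilities, token descriptors) can be captured together
with the gradient of a scalar score with respect to them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape.

    `grad` is populated by :meth:`backward` for every node in the graph
    (there is no torch-style leaf/non-leaf distinction: capture points are
    interior nodes and need their gradients retained).
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def _as_tensor(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; seeds with `grad` (ones for scalars)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape).copy()
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self.grad += _unbroadcast(g, self.data.shape)
            other.grad += _unbroadcast(g, other.data.shape)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(-g)
        return out

    def __sub__(self, other):
        return self + (-self._as_tensor(other))

    def __rsub__(self, other):
        return self._as_tensor(other) + (-self)

    def __mul__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self.grad += _unbroadcast(g * other.data, self.data.shape)
            other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self.grad += _unbroadcast(g / other.data, self.data.shape)
            other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        out._backward = bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bwd(g):
            self.grad += g * exponent * self.data ** (exponent - 1)

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self.grad += _unbroadcast(ga, a.shape)
            other.grad += _unbroadcast(gb, b.shape)

        out._backward = bwd
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(g.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(g.transpose(inv))
        return out

    def roll(self, shift, axis):
        """Cyclic roll (the shifted-window translation)."""
        out = Tensor(np.roll(self.data, shift, axis=axis), parents=(self,))
        neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift
        out._backward = lambda g: self.grad.__iadd__(np.roll(g, neg, axis=axis))
        return out

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(g * mask)
        return out

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, parents=(self,))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        out._backward = lambda g: self.grad.__iadd__(g * (phi + x * pdf))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.grad.__iadd__(g / self.data)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, parents=(self,))

        def bwd(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self.grad += p * (g - dot)

        out._backward = bwd
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        logp = z - lse
        out = Tensor(logp, parents=(self,))
        p = np.exp(logp)

        def bwd(g):
            self.grad += g - p * g.sum(axis=axis, keepdims=True)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take(self, indices: np.ndarray, axis: int = -1):
        """Gather one element per row along `axis` (label lookup)."""
        idx = np.asarray(indices)
        taken = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = Tensor(taken, parents=(self,))

        def bwd(g):
            scat = np.zeros_like(self.data)
            np.put_along_axis(scat, np.expand_dims(idx, axis), g, axis=axis)
            self.grad += scat

        out._backward = bwd
        return out

    # ----------------------------------------------------------- layer norm
    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then scale/shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = Tensor(xhat * gamma.data + beta.data, parents=(self, gamma, beta))
        n = x.shape[-1]

        def bwd(g):
            gamma.grad += _unbroadcast(g * xhat, gamma.data.shape)
            beta.grad += _unbroadcast(g, beta.data.shape)
            gx = g * gamma.data
            self.grad += inv * (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            )

        out._backward = bwd
        return out


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64))


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
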