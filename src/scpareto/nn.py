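"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the primitives the package's neural components need: a
tape-based :class:`Tensor`, dense layers, MLPs, and first-order optimizers
(plain SGD and Adam).  Everything is float64 and CPU-only; shapes follow
numpy broadcasting rules.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = [
    "Tensor",
    "concat",
    "logsumexp",
    "logaddexp",
    "Linear",
    "MLP",
    "SGD",
    "Adam",
    "flatten_grads",
    "assign_flat_grads",
    "param_vector",
    "set_param_vector",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    `data` is an ndarray (scalars are 0-d arrays); `grad` accumulates the
    gradient of the terminal scalar with respect to this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._node(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            self._accum(g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))

        return self._node(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg = np.minimum(self.data, 0.0)
        out_data = np.where(pos, self.data, alpha * np.expm1(neg))

        def backward(g):
            self._accum(g * np.where(pos, 1.0, alpha * np.exp(neg)))

        return self._node(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Hard clip; gradient is 1 inside [lo, hi] and 0 outside."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * inside)

        return self._node(np.clip(self.data, lo, hi), (self,), backward)

    def lgamma(self):
        def backward(g):
            self._accum(g * _digamma(self.data))

        return self._node(_gammaln(self.data), (self,), backward)

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- autograd driver -----------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar terminal node")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (per-step traces)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def logsumexp(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    """log Σ exp(x), stabilized by a constant (non-differentiated) max shift."""
    m = np.max(x.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = (x - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims and axis is not None:
        # squeeze through reshape to keep gradient routing simple
        out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
    elif not keepdims and axis is None:
        out = out.reshape(())
    return out


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise log(exp(a)+exp(b)) with constant max-shift stabilization."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    m = np.maximum(a.data, b.data)
    m = np.where(np.isfinite(m), m, 0.0)
    mt = Tensor(m)
    return ((a - mt).exp() + (b - mt).exp()).log() + mt


# ---------------------------------------------------------------------------
# layers


class Linear:
    """Dense layer y = xW + b with He-style Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 weight_std: float | None = None):
        std = weight_std if weight_std is not None else np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, std, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


_ACTIVATIONS = {
    "relu": lambda t: t * Tensor((t.data > 0).astype(np.float64)),
    "tanh": Tensor.tanh,
    "elu": Tensor.elu,
    "softplus": Tensor.softplus,
}


class MLP:
    """Feed-forward stack: hidden layers with `activation`, linear output."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 activation: str = "relu", weight_std: float | None = None):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [
            Linear(a, b, rng, weight_std=weight_std)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.activation = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.activation(layer(x))
        return self.layers[-1](x)

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    """Plain gradient descent: p ← p − lr · grad. Exists for exact unit tests."""

    def __init__(self, params: Iterable[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adam with a configurable denominator epsilon (default 0.01 for stability)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# flat-vector views of parameter lists (Pareto MTL composes gradients as
# single vectors across all parameters)


def flatten_grads(params: Sequence[Tensor]) -> np.ndarray:
    out = []
    for p in params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        out.append(np.asarray(g, dtype=np.float64).ravel())
    return np.concatenate(out)


def assign_flat_grads(params: Sequence[Tensor], flat: np.ndarray) -> None:
    i = 0
    for p in params:
        n = p.data.size
        p.grad = flat[i : i + n].reshape(p.data.shape).copy()
        i += n
    if i != flat.size:
        raise ValueError("flat gradient length does not match parameters")


def param_vector(params: Sequence[Tensor]) -> np.ndarray:
    return np.concatenate([p.data.ravel() for p in params])


def set_param_vector(params: Sequence[Tensor], flat: np.ndarray) -> None:
    i = 0
    for p in params:
        n = p.data.size
        p.data = flat[i : i + n].reshape(p.data.shape).copy()
        i += n
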