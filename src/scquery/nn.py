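"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements just the tensor operations required by the adversarial
autoencoder used for cell embedding: dense affine layers, the usual
activations, log-softmax, log-gamma (for the negative binomial
likelihood) and reductions, together with an RMSProp optimizer.

Gradients are accumulated by a topological-order backward sweep.
Broadcasting follows numpy semantics; gradients of broadcast operands
are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, digamma

__all__ = ["Tensor", "Linear", "MLP", "RMSProp", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        for n in topo:
            n.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def log1p(self):
        def bw(g):
            self._accum(g / (1.0 + self.data))

        return self._make(np.log1p(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bw)

    def leaky_relu(self, alpha: float = 0.1):
        out_data = np.where(self.data > 0, self.data, alpha * self.data)

        def bw(g):
            self._accum(g * np.where(self.data > 0, 1.0, alpha))

        return self._make(out_data, (self,), bw)

    def softplus(self):
        # stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * sig)

        return self._make(out_data, (self,), bw)

    def lgamma(self):
        def bw(g):
            self._accum(g * digamma(self.data))

        return self._make(gammaln(self.data), (self,), bw)

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
        out_data = self.data - lse
        sm = np.exp(out_data)

        def bw(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), bw)


# -- layers -------------------------------------------------------------------


class Linear:
    """Dense affine map with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class MLP:
    """``depth`` leaky-ReLU hidden layers followed by a linear output.

    The non-saturating activation keeps gradients alive both for
    adversarial training and for gradient-based gene attribution."""

    def __init__(self, n_in: int, hidden: int, depth: int, n_out: int,
                 rng: np.random.Generator):
        dims = [n_in] + [hidden] * depth
        self.hidden_layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.hidden_layers:
            x = layer(x).leaky_relu()
        return self.out(x)

    def hidden(self, x: Tensor) -> Tensor:
        for layer in self.hidden_layers:
            x = layer(x).leaky_relu()
        return x

    @property
    def params(self):
        ps = []
        for layer in self.hidden_layers:
            ps.extend(layer.params)
        ps.extend(self.out.params)
        return ps


class RMSProp:
    """RMSProp without momentum: cache <- rho*cache + (1-rho)*g^2."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in params]

    def step(self):
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.rho
            c += (1.0 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
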