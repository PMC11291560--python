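"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs (dense matmul, bias add,
ReLU, masked squared error, L2 penalty) plus an Adam optimizer. Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "matmul", "add_bias", "relu",
           "tanh", "masked_sq_error", "l2_penalty", "add", "Adam"]


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad=False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if self.value.ndim != 0 and self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order topological sort
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad += g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, parents=(a, b))

    def backward(g):
        _accum(a, g @ b.value.T)
        _accum(b, a.value.T @ g)

    out._backward = backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of same-shape tensors."""
    out = Tensor(a.value + b.value, parents=(a, b))

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    out._backward = backward
    return out


def add_bias(a: Tensor, bias: Tensor) -> Tensor:
    """Add a length-d bias row to every row of an (n, d) tensor."""
    out = Tensor(a.value + bias.value[None, :], parents=(a, bias))

    def backward(g):
        _accum(a, g)
        _accum(bias, g.sum(axis=0))

    out._backward = backward
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.value), parents=(a,))

    def backward(g):
        _accum(a, g * (1.0 - out.value**2))

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.value > 0
    out = Tensor(a.value * mask, parents=(a,))

    def backward(g):
        _accum(a, g * mask)

    out._backward = backward
    return out


def masked_sq_error(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """sum(mask * (pred - target)^2); mask=None means all ones."""
    diff = pred.value - target
    if mask is not None:
        diff = diff * mask
    out = Tensor(np.sum(diff * diff), parents=(pred,))

    def backward(g):
        grad = 2.0 * diff
        if mask is not None:
            grad = grad * mask  # mask is 0/1: d/dx (m*x)^2 = 2*m^2*x = 2*m*x
        _accum(pred, g * grad)

    out._backward = backward
    return out


def l2_penalty(params: list[Tensor], mu: float) -> Tensor:
    value = mu * sum(float(np.sum(p.value**2)) for p in params)
    out = Tensor(value, parents=tuple(params))

    def backward(g):
        for p in params:
            _accum(p, g * 2.0 * mu * p.value)

    out._backward = backward
    return out


class Adam:
    """Adaptive first-order optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
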