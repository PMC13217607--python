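"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network used here is a short, fixed composition of dense matrix
operations, so a small tape-based engine is sufficient: each ``Tensor``
remembers its parents and a closure that pushes the upstream gradient
back to them.  Gradients are accumulated into ``.grad`` on leaves created
with ``requires_grad=True``.

Only the operations the model needs are implemented (matmul, broadcasting
add/mul, relu, sigmoid, log, constant powers, reductions, clipping).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph traversal -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor with seed 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in t._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves reached directly (self is a leaf)
        if not self._parents and self.requires_grad and self.grad is None:
            self.grad = np.ones_like(self.value)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_val = self.value + other.value

        def bw(g):
            return ((self, _unbroadcast(g, self.value.shape)),
                    (other, _unbroadcast(g, other.value.shape)))

        return Tensor(out_val, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (as_tensor(other) * -1.0)

    def __rsub__(self, other):
        return as_tensor(other) + (self * -1.0)

    def __mul__(self, other):
        other = as_tensor(other)
        out_val = self.value * other.value

        def bw(g):
            return ((self, _unbroadcast(g * other.value, self.value.shape)),
                    (other, _unbroadcast(g * self.value, other.value.shape)))

        return Tensor(out_val, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = as_tensor(other)
        out_val = self.value @ other.value

        def bw(g):
            return ((self, g @ other.value.T),
                    (other, self.value.T @ g))

        return Tensor(out_val, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        out_val = self.value ** exponent

        def bw(g):
            return ((self, g * exponent * self.value ** (exponent - 1.0)),)

        return Tensor(out_val, parents=(self,), backward=bw)

    def __getitem__(self, idx):
        out_val = self.value[idx]

        def bw(g):
            full = np.zeros_like(self.value)
            full[idx] = g
            return ((self, full),)

        return Tensor(out_val, parents=(self,), backward=bw)

    # -- nonlinearities and reductions ----------------------------------
    def relu(self):
        mask = self.value > 0

        def bw(g):
            return ((self, g * mask),)

        return Tensor(self.value * mask, parents=(self,), backward=bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.value))

        def bw(g):
            return ((self, g * s * (1.0 - s)),)

        return Tensor(s, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            return ((self, g / self.value),)

        return Tensor(np.log(self.value), parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        mask = (self.value >= lo) & (self.value <= hi)

        def bw(g):
            return ((self, g * mask),)

        return Tensor(np.clip(self.value, lo, hi), parents=(self,), backward=bw)

    def sum(self, axis=None):
        out_val = self.value.sum(axis=axis)

        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.value.shape).copy()),)
            return ((self, np.broadcast_to(np.expand_dims(g, axis),
                                           self.value.shape).copy()),)

        return Tensor(out_val, parents=(self,), backward=bw)

    def mean(self, axis=None):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
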