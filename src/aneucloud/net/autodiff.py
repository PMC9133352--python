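"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All tensors are float32: the network is small and noise-tolerant, and
single precision roughly doubles BLAS throughput on CPU.

Just enough machinery for the point-cloud feature extractor: broadcast-aware
elementwise ops, (batched) matrix products, ReLU, max-reduction along an
axis, sums/means, and a fused softmax cross-entropy.  Gradients flow through
a topologically sorted tape; ties in ``max`` route the gradient to the first
maximising element so backward passes are deterministic.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Sequence["Tensor"] = ()

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ---- ops ----------------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        if not isinstance(other, Tensor):
            a, c = self, float(other)

            def backward_scalar(g):
                if a.requires_grad:
                    a._accumulate(g * c)

            return Tensor._make(a.data * c, (a,), backward_scalar)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def max(self, axis: int) -> "Tensor":
        """Max-reduce along `axis`; ties route gradient to the first argmax."""
        a = self
        idx = np.expand_dims(np.argmax(a.data, axis=axis), axis)
        out = np.take_along_axis(a.data, idx, axis=axis).squeeze(axis)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.put_along_axis(full, idx, np.expand_dims(g, axis), axis=axis)
                a._accumulate(full)

        return Tensor._make(out, (a,), backward)

    def sum(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

        return Tensor._make(a.data.sum(), (a,), backward)

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    def square(self) -> "Tensor":
        return self * self

    def reshape(self, *shape) -> "Tensor":
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose_last(self) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.swapaxes(g, -1, -2))

        return Tensor._make(np.swapaxes(a.data, -1, -2), (a,), backward)

    # ---- backward -----------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          weights: Optional[np.ndarray] = None) -> Tensor:
    """Weighted mean cross-entropy over a (B, C) logit matrix.

    Fused for numerical stability; `weights` is an optional per-sample
    weight vector (normalised internally to mean 1).
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    b = z.shape[0]
    w = np.ones(b, dtype=np.float32) if weights is None \
        else np.asarray(weights, dtype=np.float32)
    w = w / w.mean()
    nll = -(np.log(p[np.arange(b), labels] + 1e-30) * w).mean()

    def backward(g):
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(b), labels] -= 1.0
            grad *= (w / np.float32(b))[:, None]
            logits._accumulate((g * grad).astype(np.float32))

    return Tensor._make(np.array(nll), (logits,), backward)


class Adam:
    """Standard Adam optimiser over a parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
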