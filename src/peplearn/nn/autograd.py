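"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's neural components (heterogeneous message passing, gated
recurrent pooling, perceptron heads) are small and run on desk-scale
corpora, so they are built directly on NumPy with this compact tape-based
autodiff core rather than a heavyweight deep-learning framework.  Only the
operations the models need are implemented; gradients are accumulated into
``Tensor.grad`` by :func:`backward`.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def back(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), back)

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def back(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(-_unbroadcast(g, other.data.shape))

        return Tensor(self.data - other.data, (self, other), back)

    def __mul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def back(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), back)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)

        def back(g: np.ndarray) -> None:
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), back)

    def __neg__(self) -> "Tensor":
        def back(g: np.ndarray) -> None:
            self._accumulate(-g)

        return Tensor(-self.data, (self,), back)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *g* back down to *shape* after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g: np.ndarray) -> None:
        x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), back)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def back(g: np.ndarray) -> None:
        x._accumulate(g * (1.0 - out * out))

    return Tensor(out, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def back(g: np.ndarray) -> None:
        x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), back)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.int64)

    def back(g: np.ndarray) -> None:
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    return Tensor(x.data[idx], (x,), back)


def scatter_sum(x: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Sum rows of *x* into ``n_rows`` buckets given by *idx* (message aggregation)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = np.zeros((n_rows,) + x.data.shape[1:])
    np.add.at(out, idx, x.data)

    def back(g: np.ndarray) -> None:
        x._accumulate(g[idx])

    return Tensor(out, (x,), back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back)


def mean_rows(x: Tensor) -> Tensor:
    n = x.data.shape[0]

    def back(g: np.ndarray) -> None:
        x._accumulate(np.broadcast_to(g / n, x.data.shape).copy())

    return Tensor(x.data.mean(axis=0), (x,), back)


def max_rows(x: Tensor) -> Tensor:
    argmax = x.data.argmax(axis=0)

    def back(g: np.ndarray) -> None:
        acc = np.zeros_like(x.data)
        acc[argmax, np.arange(x.data.shape[1])] = g
        x._accumulate(acc)

    return Tensor(x.data.max(axis=0), (x,), back)


def sum_all(x: Tensor) -> Tensor:
    def back(g: np.ndarray) -> None:
        x._accumulate(np.full_like(x.data, float(g)))

    return Tensor(np.array(x.data.sum()), (x,), back)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over rows of *logits*."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = labels.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-300).mean()

    def back(g: np.ndarray) -> None:
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(float(g) * grad / n)

    return Tensor(np.array(loss), (logits,), back)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    n = diff.size

    def back(g: np.ndarray) -> None:
        pred._accumulate(float(g) * 2.0 * diff / n)

    return Tensor(np.array((diff**2).mean()), (pred,), back)


def binary_cross_entropy_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    z = logits.data
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    loss = np.mean(np.clip(z, 0, None) - z * target + np.log1p(np.exp(-np.abs(z))))
    n = z.size

    def back(g: np.ndarray) -> None:
        logits._accumulate(float(g) * (p - target) / n)

    return Tensor(np.array(loss), (logits,), back)


def backward(loss: Tensor) -> None:
    """Reverse-topological gradient accumulation from a scalar loss."""
    order: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor) -> None:
        stack = [(t, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

    visit(loss)
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
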