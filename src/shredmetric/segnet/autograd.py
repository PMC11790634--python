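"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the segmentation network needs are implemented:
affine maps, ReLU, row gathering, axis max-pooling, concatenation,
fixed-weight sparse interpolation, log-softmax and a weighted
negative-log-likelihood reduction.  Gradients are dense float64 arrays
accumulated on a tape; :meth:`Tensor.backward` runs the tape in reverse
topological order.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


class Tensor:
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

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def param(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def constant(data: np.ndarray) -> Tensor:
    return Tensor(data)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g @ w.data.T)
        if w.requires_grad:
            w.accumulate(x.data.T @ g)

    return Tensor(x.data @ w.data, (x, w), backward)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """x + b with b broadcast over all leading axes of x."""

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g)
        if b.requires_grad:
            axes = tuple(range(g.ndim - b.data.ndim))
            b.accumulate(g.sum(axis=axes))

    return Tensor(x.data + b.data, (x, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return Tensor(x.data * mask, (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = x.data.shape

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g.reshape(orig))

    return Tensor(x.data.reshape(shape), (x,), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """y[...] = x[idx[...]]; idx indexes axis 0, output shape idx.shape + x.shape[1:]."""

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx.ravel(), g.reshape(-1, *x.data.shape[1:]))
            x.accumulate(gx)

    return Tensor(x.data[idx], (x,), backward)


def max_pool_axis(x: Tensor, axis: int) -> Tensor:
    """Max over one axis, routing gradient to the (first) argmax."""
    arg = np.argmax(x.data, axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(arg, axis), axis=axis).squeeze(axis)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.put_along_axis(
                gx, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis=axis
            )
            x.accumulate(gx)

    return Tensor(out, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.accumulate(piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def weighted_sum_rows(x: Tensor, idx: np.ndarray, w: np.ndarray) -> Tensor:
    """y[n] = sum_j w[n, j] * x[idx[n, j]] — fixed-weight interpolation."""
    out = np.einsum("nj,njc->nc", w, x.data[idx])

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            contrib = w[:, :, None] * g[:, None, :]
            np.add.at(gx, idx.ravel(), contrib.reshape(-1, x.data.shape[1]))
            x.accumulate(gx)

    return Tensor(out, (x,), backward)


def log_softmax(x: Tensor) -> Tensor:
    m = x.data.max(axis=-1, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    out = shifted - lse
    softmax = np.exp(out)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g - softmax * g.sum(axis=-1, keepdims=True))

    return Tensor(out, (x,), backward)


def weighted_nll(logp: Tensor, labels: np.ndarray, weights: np.ndarray) -> Tensor:
    """Mean weighted negative log-likelihood over rows of log-probabilities."""
    n = len(labels)
    w = np.asarray(weights, dtype=np.float64)[labels]
    loss = -(w * logp.data[np.arange(n), labels]).sum() / n

    def backward(g: np.ndarray) -> None:
        if logp.requires_grad:
            gl = np.zeros_like(logp.data)
            gl[np.arange(n), labels] = -w / n
            logp.accumulate(gl * g)

    return Tensor(loss, (logp,), backward)
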