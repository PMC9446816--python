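"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the tiny transformer encoder, the affine
classification heads and the cross-entropy objective need: broadcasting
arithmetic, batched matmul, tanh/exp/log, reductions, reshape/transpose,
concatenation, fancy-index gathers (embeddings, label picking) and dropout.
Gradients accumulate in ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` along broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(grad):
            return (_unbroadcast(grad, self.shape),
                    _unbroadcast(grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda grad: (-grad,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(grad):
            return (_unbroadcast(grad * other.data, self.shape),
                    _unbroadcast(grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda grad: (
            grad * exponent * self.data ** (exponent - 1.0),
        )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(grad):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = grad @ np.swapaxes(b, -1, -2) if b.ndim > 1 else grad * b
            else:
                ga = grad @ np.swapaxes(b, -1, -2) if b.ndim > 1 else (
                    np.expand_dims(grad, -1) * b
                )
            gb = (np.swapaxes(a, -1, -2) @ grad if a.ndim > 1
                  else np.outer(a, grad))
            return (_unbroadcast(np.asarray(ga), self.shape),
                    _unbroadcast(np.asarray(gb), other.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda grad: (grad * (1.0 - value ** 2),)
        return out

    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, parents=(self,))
        out._backward = lambda grad: (grad * value,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda grad: (grad / self.data,)
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda grad: (grad.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        inverse = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._backward = lambda grad: (grad.transpose(*inverse),)
        return out

    # -- numerically stable building blocks ----------------------------------
    def softmax(self, axis=-1):
        shift = self - self.data.max(axis=axis, keepdims=True)
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis=-1):
        shift = self - self.data.max(axis=axis, keepdims=True)
        return shift - shift.exp().sum(axis=axis, keepdims=True).log()

    # -- autodiff driver -----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent in node._parents:
                stack.append((parent, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, grad in zip(node._parents, grads):
                if parent.requires_grad:
                    if parent.grad is None:
                        parent.grad = np.zeros_like(parent.data)
                    parent.grad += grad


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        return tuple(np.split(grad, splits, axis=axis))

    out._backward = backward
    return out


def gather_rows(source: Tensor, index: np.ndarray) -> Tensor:
    """Fancy-index ``source.data[index]`` with scatter-add backward.

    Used both for embedding lookup (index of token ids into an embedding
    matrix) and for picking per-example representative token vectors.
    """
    index = np.asarray(index)
    out = Tensor(source.data[index], parents=(source,))

    def backward(grad):
        full = np.zeros_like(source.data)
        np.add.at(full, index, grad)
        return (full,)

    out._backward = backward
    return out


def gather_nd(source: Tensor, *index_arrays) -> Tensor:
    """Multi-axis fancy index, e.g. ``x[batch_idx, token_idx]``."""
    idx = tuple(np.asarray(a) for a in index_arrays)
    out = Tensor(source.data[idx], parents=(source,))

    def backward(grad):
        full = np.zeros_like(source.data)
        np.add.at(full, idx, grad)
        return (full,)

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)
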