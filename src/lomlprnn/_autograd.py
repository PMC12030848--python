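"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The networks in this package are small (a handful of 1x1 convolutions, a
two-layer GRU and a two-layer perceptron), so a compact tape-based autodiff
core over float64 ``numpy`` arrays is sufficient and keeps the whole model
stack dependency-free and deterministic on a single CPU thread.

Only the primitives the model stack needs are implemented: elementwise
arithmetic with broadcasting, matrix multiplication, reductions, shape
manipulation, basic slicing, zero padding and the usual activations.
Convolutions are composed from padding, slicing and matmul in
:mod:`lomlprnn._layers`, so their gradients come for free.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; seeds with ones if ``grad`` is None."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(
                        -g * self.data / other.data ** 2, other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(
                g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                expanded = data if keepdims else np.expand_dims(data, axis)
                mask = self.data == expanded
                # split ties evenly so the gradient check stays symmetric
                counts = mask.sum(axis=axis, keepdims=True)
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * gg / counts)
            out._backward = bw
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bw
        return out

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the last two axes symmetrically."""
        if pad_h == 0 and pad_w == 0:
            return self
        widths = [(0, 0)] * (self.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        out = Tensor(np.pad(self.data, widths), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            sl = tuple([slice(None)] * (self.ndim - 2)
                       + [slice(pad_h, pad_h + self.shape[-2]),
                          slice(pad_w, pad_w + self.shape[-1])])
            out._backward = lambda g: self._accumulate(g[sl])
        return out

    # ------------------------------------------------------------ activations
    def exp(self):
        data = np.exp(self.data)
        out = Tensor(data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self):
        data = np.tanh(self.data)
        out = Tensor(data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * (1.0 - data ** 2))
        return out

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * data * (1.0 - data))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def softmax(self, axis: int = -1):
        """Numerically stable softmax composed from primitives."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])
        out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = as_tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)
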