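"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  Only the primitives the sequence models need are
implemented (broadcasting arithmetic, batched matmul, pointwise
nonlinearities, reductions, reshaping, time-axis gather/pad).  Gradients are
checked against central finite differences in the test suite.

Plain numpy arrays and python scalars mixed into expressions are treated as
constants (no gradient flows into them).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat_time"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_data(other):
    return other.data if isinstance(other, Tensor) else np.asarray(other, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents), _parents=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only valid for scalar outputs")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        od = _as_data(other)
        out_data = self.data + od
        parents = (self, other) if isinstance(other, Tensor) else (self,)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            if isinstance(other, Tensor) and other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, parents, backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        od = _as_data(other)
        out_data = self.data * od
        parents = (self, other) if isinstance(other, Tensor) else (self,)

        def backward(g):
            self._accum(_unbroadcast(g * od, self.data.shape))
            if isinstance(other, Tensor) and other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, parents, backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        od = _as_data(other)
        out_data = self.data / od
        parents = (self, other) if isinstance(other, Tensor) else (self,)

        def backward(g):
            self._accum(_unbroadcast(g / od, self.data.shape))
            if isinstance(other, Tensor) and other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (od * od), other.data.shape))

        return self._make(out_data, parents, backward)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        od = _as_data(other)
        out_data = self.data @ od
        parents = (self, other) if isinstance(other, Tensor) else (self,)

        def backward(g):
            ga = g @ np.swapaxes(od, -1, -2)
            self._accum(_unbroadcast(ga, self.data.shape))
            if isinstance(other, Tensor) and other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, parents, backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def take_time(self, index: np.ndarray):
        """Gather along the time axis of a (B, T, N) tensor.

        ``index`` has shape (T_out, k); the result has shape (B, T_out, k, N).
        Used to build convolution patches (im2col along time).
        """
        out_data = self.data[:, index, :]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (slice(None), index, slice(None)), g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def pad_time(self, before: int, after: int):
        """Zero-pad the time axis (axis 1) of a (B, T, N) tensor."""
        out_data = np.pad(self.data, ((0, 0), (before, after), (0, 0)))
        T = self.data.shape[1]

        def backward(g):
            self._accum(g[:, before:before + T, :])

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ composites
    def sqrt(self):
        return self ** 0.5

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)  # constant shift, no grad
        shifted = self - m
        lse = shifted.exp().sum(axis=axis, keepdims=True).log()
        return shifted - lse

    def softmax(self, axis=-1):
        return self.log_softmax(axis=axis).exp()


def concat_time(tensors):
    """Concatenate (B, T_i, N) tensors along the time axis (axis 1)."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=1)
    offsets = np.cumsum([0] + [d.shape[1] for d in datas])

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[:, a:b, :])

    if out.requires_grad:
        out._backward = backward
    return out
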