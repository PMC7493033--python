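"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides the ``Tensor`` class used by the neural layers in this package:
a thin dynamic-graph autodiff engine supporting the operations needed for
convolutional classifiers with batch normalization and attention (broadcasted
arithmetic, matmul, reductions, max, sigmoid, leaky ReLU, im2col-based
convolution, padding, concatenation, slicing).

All arithmetic is float64 on CPU, so runs are bit-reproducible for a fixed
seed and platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "im2col_indices"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def zero_grad(self) -> None:
        self.grad = None

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = self._lift(other)
        out = Tensor(self.data - other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(-g, other.data.shape))

        out._backward = bw
        return out

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (self._lift(other) ** -1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad or self._parents:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad or other._parents:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g)
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over a single axis; gradient splits equally among ties."""
        m = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == m).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)

        out._backward = bw
        return out

    # ------------------------------------------------------- shape / slicing
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     _parents=(self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)

        out._backward = bw
        return out

    def pad2d(self, pad_h: int, pad_w: int):
        """Zero-pad the last two axes symmetrically."""
        if pad_h == 0 and pad_w == 0:
            return self
        widths = [(0, 0)] * (self.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
        out = Tensor(np.pad(self.data, widths), requires_grad=self.requires_grad,
                     _parents=(self,))
        sl = tuple([slice(None)] * (self.ndim - 2)
                   + [slice(pad_h, self.data.shape[-2] + pad_h),
                      slice(pad_w, self.data.shape[-1] + pad_w)])

        def bw(g):
            self._accum(g[sl])

        out._backward = bw
        return out

    # ---------------------------------------------------------- nonlinearity
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bw
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * e)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g / self.data)

        out._backward = bw
        return out

    # ---------------------------------------------------------------- im2col
    def im2col(self, kh: int, kw: int):
        """Unfold (N, C, H, W) into (N, C*kh*kw, outH*outW) patch columns.

        Stride 1, no padding (pad beforehand with :meth:`pad2d`). The
        forward pass is a strided sliding-window view plus one reshape copy;
        the backward pass scatters with kh*kw vectorized slice additions.
        """
        n, c, h, w = self.data.shape
        out_h, out_w = h - kh + 1, w - kw + 1
        win = np.lib.stride_tricks.sliding_window_view(self.data, (kh, kw),
                                                       axis=(2, 3))
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw,
                                                       out_h * out_w)
        out = Tensor(cols, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            g6 = g.reshape(n, c, kh, kw, out_h, out_w)
            buf = np.zeros_like(self.data)
            for p in range(kh):
                for q in range(kw):
                    buf[:, :, p:p + out_h, q:q + out_w] += g6[:, :, p, q]
            self._accum(buf)

        out._backward = bw
        return out


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            if t.requires_grad or t._parents:
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out
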