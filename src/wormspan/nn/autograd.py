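"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: each operation records a backward
closure; :meth:`Tensor.backward` runs them in reverse topological order.
Covers exactly the operations the counting network needs — elementwise
arithmetic, broadcasting, (batched) matmul, reductions, slicing, stacking,
softmax, valid convolution and non-overlapping max pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "stack", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward requires >=2-D operands")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)
        out_data = self.data * factor

        def backward(g):
            self._accum(g * factor)

        return Tensor._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inverse))

        return Tensor._from_op(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind == "f" else float)
            np.add.at(full, idx, g)
            self._accum(full.astype(self.data.dtype, copy=False))

        return Tensor._from_op(out_data, (self,), backward)

    # -- spatial ops -----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Valid 2-D cross-correlation, stride 1.

        ``self``: (N, C, H, W); ``weight``: (F, C, KH, KW); ``bias``: (F,).
        """
        x, w = self.data, weight.data
        kh, kw = w.shape[2], w.shape[3]
        cols = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        # cols: (N, C, OH, OW, KH, KW)
        out_data = np.einsum("nchwij,fcij->nfhw", cols, w, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]

        def backward(g):
            weight._accum(np.einsum("nfhw,nchwij->fcij", g, cols, optimize=True))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.einsum("nfhw,fcij->nchwij", g, w, optimize=True)
                dx = np.zeros_like(x, dtype=g.dtype)
                oh, ow = g.shape[2], g.shape[3]
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i:i + oh, j:j + ow] += dcols[..., i, j]
                self._accum(dx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._from_op(out_data, parents, backward)

    def max_pool2d(self, k: int):
        """Non-overlapping k x k max pooling (stride == k) on (N, C, H, W)."""
        n, c, h, w = self.data.shape
        oh, ow = h // k, w // k
        x = self.data[:, :, :oh * k, :ow * k]
        windows = x.reshape(n, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
        flat = windows.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
            dx = dflat.reshape(n, c, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
            dx = dx.reshape(n, c, oh * k, ow * k)
            if (oh * k, ow * k) != (h, w):
                full = np.zeros_like(self.data)
                full[:, :, :oh * k, :ow * k] = dx
                dx = full
            self._accum(dx)

        return Tensor._from_op(out_data, (self,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)
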