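"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps a
``float32`` ndarray, records the operations applied to it, and
:meth:`Tensor.backward` accumulates gradients by walking the tape in
reverse topological order.  The op set is exactly what the capsule
segmentation network needs — elementwise arithmetic, matmul, reductions,
shape ops, 2-D (grouped/depthwise) convolution via im2col, nearest
resize, and the capsule prediction transform.  Convolutions reduce to
BLAS matmuls, so CPU training of the desk-scale model is practical.

All gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad and not self._parents:
            return  # constant leaf: no gradient needed
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS post-order (sequences can be deep: GRU over slices)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        while visit:
            node, done = visit.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    visit.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph construction helper ------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic ----------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)
        data = a.data + b.data

        def bwd(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)
        data = a.data * b.data

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)
        data = a.data / b.data

        def bwd(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        data = a.data ** p

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(data, (a,), bwd)

    # -- unary nonlinearities ------------------------------------------
    def exp(self):
        a = self
        data = np.exp(a.data)

        def bwd(g):
            a._accum(g * data)

        return Tensor._make(data, (a,), bwd)

    def log(self):
        a = self
        data = np.log(a.data)

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(data, (a,), bwd)

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / data)

        return Tensor._make(data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0
        data = a.data * mask

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(data, (a,), bwd)

    def sigmoid(self):
        a = self
        # tanh form is overflow-safe for large |x|
        data = 0.5 * (np.tanh(0.5 * a.data) + 1.0)

        def bwd(g):
            a._accum(g * data * (1.0 - data))

        return Tensor._make(data, (a,), bwd)

    def tanh(self):
        a = self
        data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - data * data))

        return Tensor._make(data, (a,), bwd)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior only."""
        a = self
        data = np.clip(a.data, lo, hi)
        mask = (a.data >= lo) & (a.data <= hi)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(data, (a,), bwd)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        data = a.data.reshape(shape)

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(data, (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        data = a.data.transpose(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(data, (a,), bwd)

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(data, (a,), bwd)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other):
        a, b = self, Tensor._coerce(other)
        data = a.data @ b.data

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.shape))
            b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(data, (a, b), bwd)

    __matmul__ = matmul

    def softmax(self, axis: int):
        """Numerically stable softmax along ``axis`` (graph-composed)."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- spatial ops ------------------------------------------------------
    def pad2d(self, pad: int):
        """Zero-pad the last two axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        data = np.pad(a.data, width)

        def bwd(g):
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            a._accum(g[sl])

        return Tensor._make(data, (a,), bwd)

    @staticmethod
    def _conv_geometry(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        return xp, ho, wo

    @staticmethod
    def _tap(arr: np.ndarray, i: int, j: int, ho: int, wo: int, stride: int):
        return arr[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride]

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation, ``x (N,C,H,W) * w (O,C,kh,kw) -> (N,O,Ho,Wo)``.

        Computed as a shift-and-add over the kh*kw taps, each tap a GEMM;
        this keeps memory flat (no im2col patch matrix) and stays in BLAS.
        """
        x, w = self, weight
        n, c, _, _ = x.shape
        o, cw, kh, kw = w.shape
        if cw != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
        xp, ho, wo = Tensor._conv_geometry(x.data, kh, kw, stride, padding)
        data = np.zeros((n, o, ho, wo), np.float32)
        for i in range(kh):
            for j in range(kw):
                sl = Tensor._tap(xp, i, j, ho, wo, stride)
                # (N,C,Ho,Wo) x (O,C) -> (N,Ho,Wo,O)
                data += np.tensordot(sl, w.data[:, :, i, j],
                                     axes=([1], [1])).transpose(0, 3, 1, 2)
        if bias is not None:
            data += bias.data.reshape(1, o, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def bwd(g):
            g = np.ascontiguousarray(g, dtype=np.float32)
            dw = np.empty_like(w.data)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    sl = Tensor._tap(xp, i, j, ho, wo, stride)
                    dw[:, :, i, j] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                    dsl = np.tensordot(g, w.data[:, :, i, j],
                                       axes=([1], [0])).transpose(0, 3, 1, 2)
                    Tensor._tap(dxp, i, j, ho, wo, stride)[...] += dsl
            w._accum(dw)
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

        return Tensor._make(data, parents, bwd)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0):
        """Per-channel conv, ``x (N,C,H,W) * w (C,kh,kw) -> (N,C,Ho,Wo)``."""
        x, w = self, weight
        n, c, _, _ = x.shape
        cw, kh, kw = w.shape
        if cw != c:
            raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")
        xp, ho, wo = Tensor._conv_geometry(x.data, kh, kw, stride, padding)
        data = np.zeros((n, c, ho, wo), np.float32)
        for i in range(kh):
            for j in range(kw):
                data += w.data[None, :, i, j, None, None] * Tensor._tap(xp, i, j, ho, wo, stride)
        if bias is not None:
            data += bias.data.reshape(1, c, 1, 1)
        parents = (x, w) if bias is None else (x, w, bias)

        def bwd(g):
            dw = np.empty_like(w.data)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    sl = Tensor._tap(xp, i, j, ho, wo, stride)
                    dw[:, i, j] = (g * sl).sum(axis=(0, 2, 3))
                    Tensor._tap(dxp, i, j, ho, wo, stride)[...] += \
                        w.data[None, :, i, j, None, None] * g
            w._accum(dw)
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

        return Tensor._make(data, parents, bwd)

    def resize_nearest(self, out_hw: tuple[int, int]):
        """Nearest-neighbour resize of the last two axes to ``out_hw``."""
        a = self
        h, w = a.shape[-2], a.shape[-1]
        oh, ow = out_hw
        ri = np.minimum((np.arange(oh) * h) // oh, h - 1)
        ci = np.minimum((np.arange(ow) * w) // ow, w - 1)
        data = a.data[..., ri[:, None], ci[None, :]]

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, (Ellipsis, ri[:, None], ci[None, :]), g)
            a._accum(full)

        return Tensor._make(data, (a,), bwd)

    def caps_transform(self, weight: "Tensor"):
        """Capsule prediction vectors ``u (N,I,di) x W (I,O,di,do) -> (N,I,O,do)``."""
        u, w = self, weight
        data = np.einsum("nid,iode->nioe", u.data, w.data, optimize=True)

        def bwd(g):
            u._accum(np.einsum("nioe,iode->nid", g, w.data, optimize=True))
            w._accum(np.einsum("nioe,nid->iode", g, u.data, optimize=True))

        return Tensor._make(data, (u, w), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, ts, bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    data = np.stack([t.data for t in ts], axis=axis)

    def bwd(g):
        for k, t in enumerate(ts):
            t._accum(np.take(g, k, axis=axis))

    return Tensor._make(data, ts, bwd)
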