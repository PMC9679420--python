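"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the 3D convolutional classifier is built on: a
tape-based :class:`Tensor` supporting the handful of differentiable
operations the network needs (broadcast arithmetic, matmul, reductions,
shape ops, pointwise nonlinearities) plus an ``im2col`` gather primitive
that turns 3D convolution into a matrix product.  Gradients are accumulated
by topological traversal of the recorded graph.

Everything is float64 and CPU-only; the package's networks are small enough
that clarity wins over throughput.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            if e == 0.0:
                return
            self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), bw)

    # -- pointwise ---------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bw)

    def exp(self):
        e = np.exp(self.data)

        def bw(g):
            self._accum(g * e)

        return self._make(e, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def bw(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        mask = self.data == m
        mask = mask / mask.sum(axis=axis, keepdims=True)  # ties split evenly

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * mask)

        out = m if keepdims else np.squeeze(m, axis=axis)
        return self._make(out, (self,), bw)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate(datas, axis=axis))

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = any(t.requires_grad for t in tensors)
        out._parents = tuple(tensors)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# im2col: 3D convolution as a gather + matmul
# ---------------------------------------------------------------------------

_COL_CACHE: dict[tuple, tuple[np.ndarray, tuple[int, ...]]] = {}


def _im2col_indices(
    cthw: tuple[int, int, int, int], kernel: tuple[int, int, int], stride: int, pad: int
):
    key = (cthw, kernel, stride, pad)
    if key not in _COL_CACHE:
        c, t, h, w = cthw
        kt, kh, kw = kernel
        tp, hp, wp = t + 2 * pad, h + 2 * pad, w + 2 * pad
        to, ho, wo = (
            (tp - kt) // stride + 1,
            (hp - kh) // stride + 1,
            (wp - kw) // stride + 1,
        )
        ci, dt, dh, dw = np.meshgrid(
            np.arange(c), np.arange(kt), np.arange(kh), np.arange(kw), indexing="ij"
        )
        kpart = (((ci * tp + dt) * hp + dh) * wp + dw).reshape(-1)  # (C*kt*kh*kw,)
        ot, oh, ow = np.meshgrid(
            np.arange(to) * stride,
            np.arange(ho) * stride,
            np.arange(wo) * stride,
            indexing="ij",
        )
        pos = ((ot * hp + oh) * wp + ow).reshape(-1)  # (L,)
        idx = kpart[:, None] + pos[None, :]
        _COL_CACHE[key] = (idx, (to, ho, wo, c * tp * hp * wp, tp, hp, wp))
    return _COL_CACHE[key]


def im2col(x: Tensor, kernel: tuple[int, int, int], stride: int, pad: int) -> Tensor:
    """Unfold (N, C, T, H, W) into convolution columns (N, C*k^3, L)."""
    n, c, t, h, w = x.shape
    idx, (to, ho, wo, size, tp, hp, wp) = _im2col_indices((c, t, h, w), kernel, stride, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    flat = xp.reshape(n, -1)
    cols = flat[:, idx]  # (N, CK, L)

    def bw(g):
        # bincount is considerably faster than np.add.at for this scatter
        offs = (np.arange(n) * size)[:, None, None]
        big = (idx[None, :, :] + offs).ravel()
        gflat = np.bincount(big, weights=g.ravel(), minlength=n * size).reshape(n, size)
        gpad = gflat.reshape(n, c, tp, hp, wp)
        x._accum(gpad[:, :, pad : pad + t, pad : pad + h, pad : pad + w])

    out = Tensor(cols)
    if x.requires_grad or x._parents:
        out.requires_grad = x.requires_grad
        out._parents = (x,)
        out._backward = bw
    return out


def conv_output_shape(
    cthw: tuple[int, int, int, int], kernel: tuple[int, int, int], stride: int, pad: int
) -> tuple[int, int, int]:
    _, meta = _im2col_indices(cthw, kernel, stride, pad)
    return meta[:3]
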