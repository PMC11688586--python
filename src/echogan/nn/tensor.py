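"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the enhancement networks need are
implemented: broadcast elementwise arithmetic, reductions, activations,
reshape/concat, and strided 2-D (transposed) convolution via im2col.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "leaky_relu",
    "relu",
    "tanh",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph -------------------------------------------------------------
    def _needs_graph(self) -> bool:
        return self.requires_grad or self._parents != ()

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide, lambda a, b, g: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return (self**-1.0) * other

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def bwd(g):
            return ((self, g * e * self.data ** (e - 1.0)),)

        return _make(out_data, (self,), bwd)

    def abs(self):
        out_data = np.abs(self.data)

        def bwd(g):
            return ((self, g * np.sign(self.data)),)

        return _make(out_data, (self,), bwd)

    def sqrt(self):
        return self**0.5

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is None:
                return ((self, np.broadcast_to(g, self.data.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return _make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            return ((self, g.reshape(old)),)

        return _make(out_data, (self,), bwd)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], bwd) -> Tensor:
    if any(p._needs_graph() for p in parents):
        return Tensor(data, _parents=tuple(parents), _backward=bwd)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, grads) -> Tensor:
    a = as_tensor(a)
    if isinstance(b, (int, float, np.integer, np.floating)):
        # python scalars follow the tensor's dtype instead of promoting to f64
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    else:
        b = as_tensor(b)
    out_data = fwd(a.data, b.data)

    def bwd(g):
        ga, gb = grads(a.data, b.data, g)
        return (
            (a, _unbroadcast(ga, a.data.shape)),
            (b, _unbroadcast(gb, b.data.shape)),
        )

    return _make(out_data, (a, b), bwd)


# -- activations ---------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        return ((x, g * mask),)

    return _make(out_data, (x,), bwd)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def bwd(g):
        return ((x, g * np.where(mask, 1.0, slope)),)

    return _make(out_data, (x,), bwd)


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def bwd(g):
        return ((x, g * (1.0 - out_data * out_data)),)

    return _make(out_data, (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    return _make(out_data, tensors, bwd)


# -- 2-D convolution ------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,OH,OW,kh,kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, xshape: tuple, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` — scatter-add patches back."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        hi = i + stride * oh
        for j in range(kw):
            wj = j + stride * ow
            out[:, :, i:hi:stride, j:wj:stride] += cols6[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Cross-correlation with weight of shape (C_out, C_in, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n = x.data.shape[0]
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}"
        )
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out = np.matmul(wmat[None], cols).reshape(n, cout, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def bwd(g):
        gflat = g.reshape(n, cout, oh * ow)
        gw = np.matmul(gflat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            weight.data.shape
        )
        gcols = np.matmul(wmat.T[None], gflat)
        gx = _col2im(gcols, x.data.shape, kh, kw, stride, padding)
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3)).reshape(bias.data.shape)))
        return tuple(grads)

    return _make(out, parents, bwd)


def conv_transpose2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """Transposed convolution; weight shape (C_in, C_out, kh, kw).

    The forward pass is the adjoint of :func:`conv2d`'s forward with the same
    stride/padding, so output side length is ``(H-1)*stride - 2*padding + kh``.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.data.shape
    wcin, cout, kh, kw = weight.data.shape
    if cin != wcin:
        raise ValueError(
            f"conv_transpose2d: input has {cin} channels, weight expects {wcin}"
        )
    ho = (h - 1) * stride - 2 * padding + kh
    wo = (w - 1) * stride - 2 * padding + kw
    xf = x.data.reshape(n, cin, h * w)
    wmat = weight.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(wmat.T[None], xf)  # (N, Cout*kh*kw, H*W)
    out = _col2im(cols, (n, cout, ho, wo), kh, kw, stride, padding)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def bwd(g):
        gcols, goh, gow = _im2col(g, kh, kw, stride, padding)
        # goh, gow recover (h, w) by construction
        gx = np.matmul(wmat[None], gcols).reshape(x.data.shape)
        gw = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0).reshape(
            weight.data.shape
        )
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3)).reshape(bias.data.shape)))
        return tuple(grads)

    return _make(out, parents, bwd)
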