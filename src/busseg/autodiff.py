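"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the package's deep-learning core: a small define-by-run tape with the
handful of differentiable operations the segmentation model needs (broadcasted
arithmetic, matrix products, 2-D convolution and its transposed counterpart,
pointwise nonlinearities, softmax, reductions and shape ops).  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.

Conventions
-----------
* Arrays keep whatever float dtype they are given; model code uses float32,
  gradient-check tests use float64.
* Only tensors created with ``requires_grad=True`` (or depending on one)
  participate in the tape; everything else is treated as a constant.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "pow_",
    "exp",
    "log",
    "tanh",
    "relu",
    "gelu",
    "sigmoid",
    "softmax",
    "matmul",
    "sum_",
    "mean_",
    "reshape",
    "transpose",
    "concat",
    "pad2d",
    "conv2d",
    "conv_transpose2d",
    "upsample_nearest2",
    "bce_with_logits_mean",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[..., None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this tensor w.r.t. every tape ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the call stack
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            else:
                node._backward(g, grads)

    # helper used by op closures to push gradient to a parent
    @staticmethod
    def _send(grads: dict[int, np.ndarray], parent: "Tensor", g: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        key = id(parent)
        if key in grads:
            grads[key] = grads[key] + g
        else:
            grads[key] = g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, grads):
        Tensor._send(grads, a, _unbroadcast(g, a.shape))
        Tensor._send(grads, b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, grads):
        Tensor._send(grads, a, _unbroadcast(g, a.shape))
        Tensor._send(grads, b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, grads):
        Tensor._send(grads, a, _unbroadcast(g * b.data, a.shape))
        Tensor._send(grads, b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g, grads):
        Tensor._send(grads, a, _unbroadcast(g / b.data, a.shape))
        Tensor._send(grads, b, _unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _make(a.data / b.data, (a, b), bw)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def bw(g, grads):
        Tensor._send(grads, a, -g)

    return _make(-a.data, (a,), bw)


def pow_(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    e = float(exponent)

    def bw(g, grads):
        Tensor._send(grads, a, g * e * a.data ** (e - 1.0))

    return _make(a.data**e, (a,), bw)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def exp(a) -> Tensor:
    a = as_tensor(a)
    y = np.exp(a.data)

    def bw(g, grads):
        Tensor._send(grads, a, g * y)

    return _make(y, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g, grads):
        Tensor._send(grads, a, g / a.data)

    return _make(np.log(a.data), (a,), bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)

    def bw(g, grads):
        Tensor._send(grads, a, g * (1.0 - y**2))

    return _make(y, (a,), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def bw(g, grads):
        Tensor._send(grads, a, g * mask)

    return _make(np.where(mask, a.data, 0.0), (a,), bw)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """Tanh-approximation GELU."""
    a = as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def bw(g, grads):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
        dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
        Tensor._send(grads, a, g * dy)

    return _make(y, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g, grads):
        Tensor._send(grads, a, g * y * (1.0 - y))

    return _make(y, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g, grads):
        dot = (g * y).sum(axis=axis, keepdims=True)
        Tensor._send(grads, a, y * (g - dot))

    return _make(y, (a,), bw)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    y = a.data @ b.data

    def bw(g, grads):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            Tensor._send(grads, a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.outer(a.data, g) if g.ndim == 1 else a.data[:, None] @ g[None]
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
            Tensor._send(grads, b, _unbroadcast(gb, b.shape))

    return _make(y, (a, b), bw)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    y = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g, grads):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(ax % a.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.shape)]
            g = g.reshape(shape)
        Tensor._send(grads, a, np.broadcast_to(g, a.shape).copy())

    return _make(y, (a,), bw)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def bw(g, grads):
        Tensor._send(grads, a, g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def bw(g, grads):
        Tensor._send(grads, a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    y = np.concatenate([t.data for t in ts], axis=axis)

    def bw(g, grads):
        start = 0
        for t, s in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            Tensor._send(grads, t, g[tuple(sl)])
            start += s

    return _make(y, ts, bw)


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the last two axes of a (B, C, H, W) tensor."""
    a = as_tensor(a)
    if pad == 0:
        return a
    y = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

    def bw(g, grads):
        Tensor._send(grads, a, g[:, :, pad:-pad, pad:-pad])

    return _make(y, (a,), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Plain correlation: x (B,Ci,H,W), w (Co,Ci,kh,kw) -> (B,Co,Ho,Wo)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, Ci, H, W = x.shape
    Co, _, kh, kw = w.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,Ci,Ho,Wo,kh,kw)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Ci * kh * kw)
    out = col @ w.reshape(Co, Ci * kh * kw).T
    return out.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2), col


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation with optional bias.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,).
    """
    x, w = as_tensor(x), as_tensor(w)
    bias = as_tensor(b) if b is not None else None
    y, col = _conv_fwd(x.data, w.data, stride, padding)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    B, Ci, H, W = x.shape
    Co, _, kh, kw = w.shape
    _, _, Ho, Wo = y.shape

    def bw(g, grads):
        if bias is not None and bias.requires_grad:
            Tensor._send(grads, bias, g.sum(axis=(0, 2, 3)))
        gflat = None
        if w.requires_grad or x.requires_grad:
            gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, Co)
        if w.requires_grad:
            gw = gflat.T @ col.reshape(B * Ho * Wo, Ci * kh * kw)
            Tensor._send(grads, w, gw.reshape(w.shape))
        if x.requires_grad:
            # col2im: one matmul, then strided scatter per kernel offset
            gcol = gflat @ w.data.reshape(Co, Ci * kh * kw)
            gcol = gcol.reshape(B, Ho, Wo, Ci, kh, kw)
            gxp = np.zeros((B, Ci, H + 2 * padding, W + 2 * padding), dtype=g.dtype)
            for p in range(kh):
                for q in range(kw):
                    gxp[:, :, p : p + Ho * stride : stride,
                        q : q + Wo * stride : stride] += gcol[..., p, q].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            Tensor._send(grads, x, gxp)

    parents = (x, w) if bias is None else (x, w, bias)
    return _make(y, parents, bw)


def conv_transpose2d(x, w, b=None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size equal to stride (no overlap).

    ``x``: (B, Cin, H, W); ``w``: (Cin, Cout, s, s) -> (B, Cout, H*s, W*s).
    """
    x, w = as_tensor(x), as_tensor(w)
    bias = as_tensor(b) if b is not None else None
    s = stride
    B, Ci, H, W = x.shape
    _, Co, _, _ = w.shape
    y = np.einsum("bchw,copq->bohpwq", x.data, w.data).reshape(B, Co, H * s, W * s)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def bw(g, grads):
        gblk = g.reshape(B, Co, H, s, W, s)
        if bias is not None and bias.requires_grad:
            Tensor._send(grads, bias, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            Tensor._send(grads, w, np.einsum("bohpwq,bchw->copq", gblk, x.data))
        if x.requires_grad:
            Tensor._send(grads, x, np.einsum("bohpwq,copq->bchw", gblk, w.data))

    parents = (x, w) if bias is None else (x, w, bias)
    return _make(y, parents, bw)


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (B, C, H, W)."""
    x = as_tensor(x)
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    B, C, H, W = x.shape

    def bw(g, grads):
        Tensor._send(grads, x, g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _make(y, (x,), bw)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits_mean(logits, targets) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    x = as_tensor(logits)
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets)
    z = x.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bw(g, grads):
        p = 1.0 / (1.0 + np.exp(-z))
        Tensor._send(grads, x, g * (p - t) / n)

    return _make(np.asarray(loss.mean()), (x,), bw)
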