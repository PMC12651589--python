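"""Neural-network building blocks on top of :mod:`busseg.autodiff`.

Contains the module system (parameter discovery, state dict, checksums), the
layers the segmentation model is assembled from, and the AdamW optimizer.
"""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "ChannelNorm",
    "LayerNorm",
    "MultiheadSelfAttention",
    "TransformerBlock",
    "ResidualBlock",
    "AdamW",
    "parameter_checksum",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data), requires_grad=requires_grad)


class Module:
    """Tiny nn.Module analogue: attribute-based parameter discovery."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(p.data.dtype).copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter_checksum(module: Module, only_frozen: bool = False) -> str:
    """SHA-256 over parameter bytes; used to verify frozen components."""
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        if only_frozen and p.requires_grad:
            continue
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float32):
        if zero_init:
            w = np.zeros((in_features, out_features), dtype=dtype)
        else:
            w = _he_normal(rng, (in_features, out_features), in_features, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.weight.shape[0]:
            raise ValueError(
                f"Linear: input width {x.shape[-1]} != expected {self.weight.shape[0]}")
        return ad.add(ad.matmul(x, self.weight), self.bias)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, zero_init: bool = False,
                 dtype=np.float32):
        if padding is None:
            padding = kernel // 2
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=dtype)
        else:
            w = _he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Non-overlapping transposed convolution: kernel size == stride."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = _he_normal(rng, (in_ch, out_ch, stride, stride), in_ch, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class ChannelNorm(Module):
    """Per-sample normalization over (C, H, W) with per-channel affine.

    Equivalent to group normalization with a single group; has no running
    statistics, so train and eval behaviour are identical and deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gain = Parameter(np.ones((1, channels, 1, 1), dtype=dtype))
        self.bias = Parameter(np.zeros((1, channels, 1, 1), dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean_(x, axis=(1, 2, 3), keepdims=True)
        xc = ad.sub(x, mu)
        var = ad.mean_(ad.mul(xc, xc), axis=(1, 2, 3), keepdims=True)
        inv = ad.pow_(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), self.gain), self.bias)


class LayerNorm(Module):
    """Normalization over the last axis (token width)."""

    def __init__(self, width: int, eps: float = 1e-5, dtype=np.float32):
        self.gain = Parameter(np.ones(width, dtype=dtype))
        self.bias = Parameter(np.zeros(width, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean_(x, axis=-1, keepdims=True)
        xc = ad.sub(x, mu)
        var = ad.mean_(ad.mul(xc, xc), axis=-1, keepdims=True)
        inv = ad.pow_(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), self.gain), self.bias)


class MultiheadSelfAttention(Module):
    def __init__(self, width: int, n_heads: int, rng: np.random.Generator,
                 zero_init_out: bool = True, dtype=np.float32):
        if width % n_heads:
            raise ValueError("width must be divisible by n_heads")
        self.qkv = Linear(width, 3 * width, rng, dtype=dtype)
        self.out = Linear(width, width, rng, zero_init=zero_init_out, dtype=dtype)
        self.n_heads = n_heads
        self.width = width
        self._last_attn: np.ndarray | None = None  # (B, heads, N, N), diagnostics

    def forward(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        hd = C // self.n_heads
        qkv = self.qkv(x)  # (B, N, 3C)
        qkv = ad.reshape(qkv, (B, N, 3, self.n_heads, hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, heads, N, hd)
        q, k, v = _split3(qkv)
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(hd))
        attn = ad.softmax(scores, axis=-1)
        self._last_attn = attn.data
        ctx = ad.matmul(attn, v)  # (B, heads, N, hd)
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (B, N, C))
        return self.out(ctx)


def _split3(qkv: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split the leading axis of a (3, ...) tensor."""
    def take(i):
        def bw(g, grads, i=i):
            full = np.zeros(qkv.shape, dtype=g.dtype)
            full[i] = g
            Tensor._send(grads, qkv, full)
        from .autodiff import _make
        return _make(qkv.data[i], (qkv,), bw)
    return take(0), take(1), take(2)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block with learned positional embedding.

    Output projections of both the attention and the MLP are zero-initialized,
    so a freshly built block is the identity map.
    """

    def __init__(self, width: int, n_tokens: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 2, dtype=np.float32):
        self.pos = Parameter((rng.standard_normal((1, n_tokens, width)) * 0.02).astype(dtype))
        self.norm1 = LayerNorm(width, dtype=dtype)
        self.attn = MultiheadSelfAttention(width, n_heads, rng, zero_init_out=True, dtype=dtype)
        self.norm2 = LayerNorm(width, dtype=dtype)
        self.fc1 = Linear(width, mlp_ratio * width, rng, dtype=dtype)
        self.fc2 = Linear(mlp_ratio * width, width, rng, zero_init=True, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.add(x, self.attn(self.norm1(ad.add(x, self.pos))))
        return ad.add(h, self.fc2(ad.gelu(self.fc1(self.norm2(h)))))


class ResidualBlock(Module):
    """conv-norm-relu-conv residual block; final conv zero-initialized so the
    block starts as the identity."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, 3, rng, dtype=dtype)
        self.norm = ChannelNorm(channels, dtype=dtype)
        self.conv2 = Conv2d(channels, channels, 3, rng, zero_init=True, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.norm(self.conv1(x)))
        return ad.add(x, self.conv2(h))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - lr * (update + self.weight_decay * p.data)).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
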