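"""Global Feature Extractor: frozen ViT tokens -> reduced, prompt-conditioned
tokens -> spatial global feature map.

The vision backbone is frozen, so it runs as plain numpy outside the autodiff
tape; only the per-layer token reducers, the prompt-conditioning maps, the
transposed-convolution projection, and the branch's SFA site are trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import PATCH_SIZE
from .layers import ChannelNorm, Conv2d, ConvTranspose2d, Linear, Module, Parameter
from .sfa import SFASite

__all__ = ["TokenStack", "ReducedTokens", "VisionBackbone", "ToyViT", "GlobalBranch"]


@dataclass
class TokenStack:
    """Token sequences (B, N, D) from the selected backbone layers.

    Index 0 of every sequence is the class token; N = 1 + (side/16)^2.
    """

    layers: dict[int, np.ndarray]
    layer_ids: tuple[int, ...]
    n_tokens: int
    width: int

    def __post_init__(self) -> None:
        for j, z in self.layers.items():
            if z.shape[1] != self.n_tokens or z.shape[2] != self.width:
                raise ValueError(f"layer {j}: inconsistent token stack shape {z.shape}")


@dataclass
class ReducedTokens:
    """Aggregated patch tokens (B, N-1, r); class token already removed."""

    values: Tensor
    conditioned: bool = False
    extra: dict = field(default_factory=dict)


@runtime_checkable
class VisionBackbone(Protocol):
    patch_size: int
    width: int
    n_layers: int

    def tokens(self, images: np.ndarray, layer_ids: tuple[int, ...]) -> TokenStack: ...


class ToyViT:
    """Small frozen vision transformer used for offline testing and training.

    Deterministic given its seed: patch embedding, class token, per-grid-size
    positional embeddings, and pre-norm transformer blocks are all drawn from
    a seeded generator and never updated.  Layer id 0 is the patch-embedding
    output; ids 1..n_layers are the block outputs.
    """

    def __init__(self, width: int = 48, n_layers: int = 2, n_heads: int = 4,
                 seed: int = 0, patch_size: int = PATCH_SIZE):
        self.width = width
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.patch_size = patch_size
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, width, n_layers]))
        p = patch_size
        fan = 3 * p * p
        self._wpe = (rng.standard_normal((fan, width)) / np.sqrt(fan)).astype(np.float32)
        self._cls = (rng.standard_normal((1, 1, width)) * 0.02).astype(np.float32)
        self._blocks = []
        for _ in range(n_layers):
            blk = {
                "ln1": _ln_params(rng, width),
                "qkv": (rng.standard_normal((width, 3 * width)) / np.sqrt(width)).astype(np.float32),
                "out": (rng.standard_normal((width, width)) / np.sqrt(width)).astype(np.float32),
                "ln2": _ln_params(rng, width),
                "fc1": (rng.standard_normal((width, 2 * width)) / np.sqrt(width)).astype(np.float32),
                "fc2": (rng.standard_normal((2 * width, width)) / np.sqrt(2 * width)).astype(np.float32),
            }
            self._blocks.append(blk)
        self._pos_cache: dict[int, np.ndarray] = {}
        self._pos_rng_seed = seed

    def _pos(self, n_tokens: int) -> np.ndarray:
        if n_tokens not in self._pos_cache:
            rng = np.random.default_rng(
                np.random.SeedSequence([self._pos_rng_seed, 7919, n_tokens]))
            self._pos_cache[n_tokens] = (
                rng.standard_normal((1, n_tokens, self.width)) * 0.02).astype(np.float32)
        return self._pos_cache[n_tokens]

    def tokens(self, images: np.ndarray, layer_ids: tuple[int, ...]) -> TokenStack:
        B, C, H, W = images.shape
        p = self.patch_size
        if H % p or W % p:
            raise ValueError(f"image side must be divisible by the patch size {p}")
        g_h, g_w = H // p, W // p
        patches = images.reshape(B, C, g_h, p, g_w, p).transpose(0, 2, 4, 1, 3, 5)
        patches = patches.reshape(B, g_h * g_w, C * p * p).astype(np.float32)
        x = patches @ self._wpe
        x = np.concatenate([np.repeat(self._cls, B, axis=0), x], axis=1)
        n = x.shape[1]
        x = x + self._pos(n)
        for j in layer_ids:
            if not 0 <= j <= self.n_layers:
                raise ValueError(f"layer id {j} outside 0..{self.n_layers}")
        stacks: dict[int, np.ndarray] = {}
        if 0 in layer_ids:
            stacks[0] = x.copy()
        for depth, blk in enumerate(self._blocks, start=1):
            x = x + _np_attention(_np_layernorm(x, *blk["ln1"]), blk["qkv"], blk["out"],
                                  self.n_heads)
            h = _np_layernorm(x, *blk["ln2"])
            x = x + np.maximum(h @ blk["fc1"], 0.0) @ blk["fc2"]
            if depth in layer_ids:
                stacks[depth] = x.copy()
        return TokenStack(layers=stacks, layer_ids=tuple(layer_ids),
                          n_tokens=n, width=self.width)


def _ln_params(rng: np.random.Generator, width: int):
    return (np.ones(width, dtype=np.float32), np.zeros(width, dtype=np.float32))


def _np_layernorm(x: np.ndarray, gain: np.ndarray, bias: np.ndarray,
                  eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gain + bias


def _np_attention(x: np.ndarray, wqkv: np.ndarray, wout: np.ndarray,
                  n_heads: int) -> np.ndarray:
    B, N, C = x.shape
    hd = C // n_heads
    qkv = (x @ wqkv).reshape(B, N, 3, n_heads, hd).transpose(2, 0, 3, 1, 4)
    q, k, v = qkv[0], qkv[1], qkv[2]
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(hd)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, N, C)
    return ctx @ wout


class GlobalBranch(Module):
    """Trainable reduction, conditioning, and projection over frozen ViT tokens."""

    def __init__(self, backbone: VisionBackbone, layer_ids: tuple[int, ...],
                 reduced_width: int, cond_width: int, out_channels: int,
                 rng: np.random.Generator, residual_sfa: bool = True,
                 token_softmax: bool = False, n_upsample: int = 4, dtype=np.float32):
        self.backbone = backbone  # frozen; not a Module, holds no Parameters
        self.layer_ids = tuple(layer_ids)
        self.reduced_width = reduced_width
        self.out_channels = out_channels
        self.token_softmax = token_softmax
        self.reducers = [Linear(backbone.width, reduced_width, rng, dtype=dtype)
                         for _ in self.layer_ids]
        # conditioning starts as the identity: mul-vector 1, add-vector 0
        self.w_mul = Linear(cond_width, reduced_width, rng, zero_init=True, dtype=dtype)
        self.w_mul.bias = Parameter(np.ones(reduced_width, dtype=dtype))
        self.w_add = Linear(cond_width, reduced_width, rng, zero_init=True, dtype=dtype)
        self.upsamples = []
        self.upnorms = []
        for _ in range(n_upsample):
            self.upsamples.append(ConvTranspose2d(reduced_width, reduced_width, 2, rng,
                                                  dtype=dtype))
            self.upnorms.append(ChannelNorm(reduced_width, dtype=dtype))
        self.proj_out = Conv2d(reduced_width, out_channels, 1, rng, dtype=dtype)
        self.sfa = SFASite("global_out", out_channels, cond_width, rng,
                           residual=residual_sfa, dtype=dtype)

    # -- stages ---------------------------------------------------------------
    def encode_image_tokens(self, images: np.ndarray) -> TokenStack:
        if images.shape[-1] % self.backbone.patch_size:
            raise ValueError("image side must be divisible by the patch size")
        return self.backbone.tokens(images, self.layer_ids)

    def reduce_and_aggregate(self, stack: TokenStack) -> ReducedTokens:
        missing = [j for j in stack.layer_ids if j not in stack.layers]
        if missing:
            raise KeyError(f"token stack lacks layers {missing}")
        agg: Tensor | None = None
        for reducer, j in zip(self.reducers, self.layer_ids):
            patch_tokens = stack.layers[j][:, 1:, :]  # class token removed
            reduced = reducer(ad.Tensor(patch_tokens))
            agg = reduced if agg is None else ad.add(agg, reduced)
        if self.token_softmax:
            agg = ad.softmax(agg, axis=1)
        return ReducedTokens(values=agg, conditioned=False)

    def condition_tokens(self, tokens: ReducedTokens, ec_proj: Tensor) -> ReducedTokens:
        """Channel-wise affine conditioning of the aggregated tokens (FiLM form)."""
        if tokens.conditioned:
            raise RuntimeError("tokens are already conditioned")
        mul = self.w_mul(ec_proj)  # (B, r)
        addv = self.w_add(ec_proj)
        B, r = mul.shape
        mul3 = ad.reshape(mul, (B, 1, r))
        add3 = ad.reshape(addv, (B, 1, r))
        out = ad.add(ad.mul(mul3, tokens.values), add3)
        return ReducedTokens(values=out, conditioned=True)

    def tokens_to_map(self, tokens: ReducedTokens) -> Tensor:
        values = tokens.values
        B, n_patch, r = values.shape
        g = int(round(np.sqrt(n_patch)))
        if g * g != n_patch:
            raise ValueError(f"token count {n_patch} is not a perfect square")
        x = ad.transpose(ad.reshape(values, (B, g, g, r)), (0, 3, 1, 2))
        for up, norm in zip(self.upsamples, self.upnorms):
            x = ad.relu(norm(up(x)))
        return self.proj_out(x)

    def forward(self, images: np.ndarray, ec_proj: Tensor, use_sfa: bool = True) -> Tensor:
        """Full path: encode -> reduce -> condition -> map -> SFA."""
        stack = self.encode_image_tokens(images)
        tokens = self.reduce_and_aggregate(stack)
        if use_sfa:
            tokens = self.condition_tokens(tokens, ec_proj)
        fg = self.tokens_to_map(tokens)
        if use_sfa:
            fg = self.sfa(fg, ec_proj)
        return fg
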