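"""Local Feature Extractor: five-stage convolutional encoder with transformer
blocks at the deep stages, and a U-Net-style decoder modulated by the local
prompt through SFA.

SFA sites (all conditioned on the projected local-prompt embedding):
the attention-refined stage-4 skip, the first three decoder up blocks, and a
final site on the 32-channel output map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import ChannelNorm, Conv2d, Module, ResidualBlock, TransformerBlock
from .sfa import SFASite

__all__ = ["EncoderPyramid", "DecoderStates", "LocalBranch"]


@dataclass
class EncoderPyramid:
    """Feature maps at strides 2, 4, 8, 16, 32 relative to the input."""

    enc1: Tensor
    enc2: Tensor
    enc3: Tensor
    enc4: Tensor
    enc5: Tensor

    def as_tuple(self):
        return (self.enc1, self.enc2, self.enc3, self.enc4, self.enc5)


@dataclass
class DecoderStates:
    dec4: Tensor
    dec3: Tensor
    dec2: Tensor
    dec1: Tensor
    final_map: Tensor


class _DownStage(Module):
    """stride-2 conv + norm + relu followed by a residual block."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        self.down = Conv2d(in_ch, out_ch, 3, rng, stride=2, dtype=dtype)
        self.norm = ChannelNorm(out_ch, dtype=dtype)
        self.block = ResidualBlock(out_ch, rng, dtype=dtype)

    def forward(self, x):
        return self.block(ad.relu(self.norm(self.down(x))))


class _UpBlock(Module):
    """2x nearest upsample -> concat skip -> two conv+norm+relu layers."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, rng, dtype=np.float32):
        self.conv1 = Conv2d(in_ch + skip_ch, out_ch, 3, rng, dtype=dtype)
        self.norm1 = ChannelNorm(out_ch, dtype=dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, dtype=dtype)
        self.norm2 = ChannelNorm(out_ch, dtype=dtype)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = ad.upsample_nearest2(x)
        if x.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"up block misalignment: input {x.shape[2:]} vs skip {skip.shape[2:]}")
        x = ad.concat([x, skip], axis=1)
        x = ad.relu(self.norm1(self.conv1(x)))
        return ad.relu(self.norm2(self.conv2(x)))


class LocalBranch(Module):
    """Trainable encoder-decoder emitting a boundary-preserving local map.

    ``widths`` are the channel counts of the five encoder stages; the decoder
    mirrors them.  ``image_side`` fixes the token counts of the deep attention
    blocks (the positional embeddings are learned per grid size).
    """

    def __init__(self, image_side: int, widths: tuple[int, ...], out_channels: int,
                 cond_width: int, rng: np.random.Generator, n_heads: int = 4,
                 residual_sfa: bool = True, final_upsample: bool = True,
                 dtype=np.float32):
        if image_side % 32:
            raise ValueError("input side must be divisible by 32 (encoder stride)")
        if len(widths) != 5:
            raise ValueError("widths must list five encoder stages")
        w1, w2, w3, w4, w5 = widths
        self.widths = tuple(widths)
        self.out_channels = out_channels
        self.final_upsample = final_upsample

        self.stem = Conv2d(3, w1, 3, rng, stride=2, dtype=dtype)
        self.stem_norm = ChannelNorm(w1, dtype=dtype)
        self.stage2 = _DownStage(w1, w2, rng, dtype=dtype)
        self.stage3 = _DownStage(w2, w3, rng, dtype=dtype)
        self.stage4 = _DownStage(w3, w4, rng, dtype=dtype)
        self.stage5 = _DownStage(w4, w5, rng, dtype=dtype)

        s4 = image_side // 16
        s5 = image_side // 32
        self.attn4 = TransformerBlock(w4, s4 * s4, n_heads, rng, dtype=dtype)
        self.attn5 = TransformerBlock(w5, s5 * s5, n_heads, rng, dtype=dtype)

        self.up4 = _UpBlock(w5, w4, w4, rng, dtype=dtype)
        self.up3 = _UpBlock(w4, w3, w3, rng, dtype=dtype)
        self.up2 = _UpBlock(w3, w2, w2, rng, dtype=dtype)
        self.up1 = _UpBlock(w2, w1, w1, rng, dtype=dtype)
        self.final_conv = Conv2d(w1, w1, 3, rng, dtype=dtype)
        self.final_norm = ChannelNorm(w1, dtype=dtype)
        self.final_proj = Conv2d(w1, out_channels, 1, rng, dtype=dtype)

        self.sfa_enc4 = SFASite("local_enc4", w4, cond_width, rng, residual_sfa, dtype)
        self.sfa_dec4 = SFASite("local_dec4", w4, cond_width, rng, residual_sfa, dtype)
        self.sfa_dec3 = SFASite("local_dec3", w3, cond_width, rng, residual_sfa, dtype)
        self.sfa_dec2 = SFASite("local_dec2", w2, cond_width, rng, residual_sfa, dtype)
        self.sfa_out = SFASite("local_out", out_channels, cond_width, rng,
                               residual_sfa, dtype)

    # -- stages ---------------------------------------------------------------
    def encode_local(self, images: np.ndarray) -> EncoderPyramid:
        if images.shape[-1] % 32 or images.shape[-2] % 32:
            raise ValueError("input side must be divisible by 32 (encoder stride)")
        x = ad.relu(self.stem_norm(self.stem(ad.Tensor(np.asarray(images, dtype=np.float32)))))
        enc1 = x
        enc2 = self.stage2(enc1)
        enc3 = self.stage3(enc2)
        enc4 = self.stage4(enc3)
        enc5 = self.stage5(enc4)
        return EncoderPyramid(enc1, enc2, enc3, enc4, enc5)

    def apply_deep_attention(self, pyramid: EncoderPyramid) -> EncoderPyramid:
        """Self-attention refinement of stage four and the bottleneck."""
        enc4 = _attend_2d(self.attn4, pyramid.enc4)
        enc5 = _attend_2d(self.attn5, pyramid.enc5)
        return EncoderPyramid(pyramid.enc1, pyramid.enc2, pyramid.enc3, enc4, enc5)

    def decode_local(self, pyramid: EncoderPyramid, el_proj: Tensor,
                     use_sfa: bool = True) -> DecoderStates:
        enc4 = self.sfa_enc4(pyramid.enc4, el_proj) if use_sfa else pyramid.enc4
        dec4 = self.up4(pyramid.enc5, enc4)
        dec4s = self.sfa_dec4(dec4, el_proj) if use_sfa else dec4
        dec3 = self.up3(dec4s, pyramid.enc3)
        dec3s = self.sfa_dec3(dec3, el_proj) if use_sfa else dec3
        dec2 = self.up2(dec3s, pyramid.enc2)
        dec2s = self.sfa_dec2(dec2, el_proj) if use_sfa else dec2
        dec1 = self.up1(dec2s, pyramid.enc1)
        x = dec1
        if self.final_upsample:
            x = ad.upsample_nearest2(x)
        x = ad.relu(self.final_norm(self.final_conv(x)))
        final = self.final_proj(x)
        return DecoderStates(dec4=dec4, dec3=dec3, dec2=dec2, dec1=dec1, final_map=final)

    def forward(self, images: np.ndarray, el_proj: Tensor, use_sfa: bool = True) -> Tensor:
        """Full path; output (B, out_channels, h, w) aligned with the global map."""
        pyramid = self.apply_deep_attention(self.encode_local(images))
        states = self.decode_local(pyramid, el_proj, use_sfa=use_sfa)
        fl = states.final_map
        if use_sfa:
            fl = self.sfa_out(fl, el_proj)
        return fl


def _attend_2d(block: TransformerBlock, feat: Tensor) -> Tensor:
    B, C, h, w = feat.shape
    tokens = ad.transpose(ad.reshape(feat, (B, C, h * w)), (0, 2, 1))
    out = block(tokens)
    return ad.reshape(ad.transpose(out, (0, 2, 1)), (B, C, h, w))
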