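"""Semantic Feature Adjustment: prompt-conditioned channel-wise FiLM.

Each conditioning site owns a small two-layer perceptron that maps the
projected prompt embedding (width d) to 2*C values, split into a per-channel
scale gamma and shift beta, broadcast over spatial positions:

    F_hat = gamma * F + beta            (affine form)
    F_out = F_hat + F                   (optional additive skip)

Initialization makes every site the identity map for *any* embedding: the
final layer's weights are zero and its bias is (1...1, 0...0) in the plain
affine form, or (0...0, 0...0) when the additive skip is enabled (so that
F_out = 0*F + 0 + F = F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Linear, Module, Parameter

__all__ = ["FiLMParams", "SFASite", "apply_film"]


@dataclass
class FiLMParams:
    """Per-sample, per-channel scale and shift, each of shape (B, C)."""

    gamma: Tensor
    beta: Tensor
    stage_id: str

    @property
    def channels(self) -> int:
        return self.gamma.shape[-1]


class SFASite(Module):
    """One SFA instance bound to a stage with channel width C."""

    def __init__(self, stage_id: str, channels: int, cond_width: int,
                 rng: np.random.Generator, residual: bool = True, dtype=np.float32):
        self.stage_id = stage_id
        self.channels = channels
        self.residual = residual
        self.fc1 = Linear(cond_width, cond_width, rng, dtype=dtype)
        self.fc2 = Linear(cond_width, 2 * channels, rng, zero_init=True, dtype=dtype)
        gamma_init = 0.0 if residual else 1.0
        bias = np.concatenate([
            np.full(channels, gamma_init, dtype=dtype), np.zeros(channels, dtype=dtype)])
        self.fc2.bias = Parameter(bias)

    def predict_film(self, embedding: Tensor | np.ndarray) -> FiLMParams:
        """Two-layer MLP d -> d -> 2C, split into gamma and beta."""
        emb = ad.as_tensor(embedding)
        z = self.fc2(ad.relu(self.fc1(emb)))  # (B, 2C)
        gamma = _slice_last(z, 0, self.channels)
        beta = _slice_last(z, self.channels, 2 * self.channels)
        return FiLMParams(gamma=gamma, beta=beta, stage_id=self.stage_id)

    def forward(self, feature: Tensor | np.ndarray, embedding: Tensor | np.ndarray) -> Tensor:
        params = self.predict_film(embedding)
        return apply_film(feature, params, residual=self.residual)


def _slice_last(t: Tensor, start: int, stop: int) -> Tensor:
    from .autodiff import _make

    def bw(g, grads):
        full = np.zeros(t.shape, dtype=g.dtype)
        full[..., start:stop] = g
        Tensor._send(grads, t, full)

    return _make(t.data[..., start:stop], (t,), bw)


def apply_film(feature: Tensor | np.ndarray, params: FiLMParams,
               residual: bool = False) -> Tensor:
    """Apply channel-wise scale/shift, broadcast over the spatial grid.

    ``feature`` is (B, C, h, w); gamma/beta are (B, C) and are reshaped to
    (B, C, 1, 1).  With ``residual`` the input is added back (additive skip).
    """
    feature = ad.as_tensor(feature)
    B, C = feature.shape[0], feature.shape[1]
    if params.channels != C:
        raise ValueError(
            f"FiLM channel mismatch at stage {params.stage_id!r}: "
            f"params have {params.channels}, feature has {C}")
    gamma = ad.reshape(ad.as_tensor(params.gamma), (B, C, 1, 1))
    beta = ad.reshape(ad.as_tensor(params.beta), (B, C, 1, 1))
    out = ad.add(ad.mul(gamma, feature), beta)
    if residual:
        out = ad.add(out, feature)
    return out
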