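"""Model assembly: branch fusion, prediction head, ablation toggles, losses,
and the two-pass (location-bootstrap) inference procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig, spawn_rng
from .global_branch import GlobalBranch, ToyViT, VisionBackbone
from .layers import Conv2d, Module, Parameter, ResidualBlock
from .local_branch import LocalBranch
from .prompts import (
    LesionMetadata,
    SizeBins,
    build_global_prompt,
    build_local_prompt,
    estimate_location_from_probmap,
    quadrant_token,
    size_token,
)
from .text_embedding import TextEncoder, encode_batch

__all__ = [
    "ModelConfig",
    "SegmentationResult",
    "DualPromptSegModel",
    "build_model",
    "predict_two_pass",
    "soft_dice_loss",
    "segmentation_loss",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters and ablation switches.

    ``cg``/``cl`` are the global/local branch output widths (64 and 32 by
    default); ``embed_dim`` is the text-encoder width e, ``cond_width`` the
    shared conditioning width d, and ``reduced_width`` the token width r of
    the aggregated ViT tokens.  ``logit_gain`` is a fixed multiplier on the
    head's 1x1-convolution output so probabilities can saturate within short
    cosine schedules at small learning rates.
    """

    use_gfe: bool = True
    use_lfe: bool = True
    use_sfa: bool = True
    embed_dim: int = 64
    cond_width: int = 64
    reduced_width: int = 64
    layer_set: tuple[int, ...] = (1, 2)
    cg: int = 64
    cl: int = 32
    residual_sfa: bool = True
    logit_gain: float = 20.0
    image_side: int = 352
    local_widths: tuple[int, ...] = (32, 64, 128, 256, 256)
    vit_width: int = 48
    vit_layers: int = 2
    vit_heads: int = 4
    local_heads: int = 4
    token_softmax: bool = False
    working_stride: int = 1  # 1: branches emit full-resolution maps; 2: half

    def __post_init__(self) -> None:
        if not (self.use_gfe or self.use_lfe):
            raise ValueError("at least one branch must be enabled")
        for name in ("embed_dim", "cond_width", "reduced_width", "cg", "cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.working_stride not in (1, 2):
            raise ValueError("working_stride must be 1 or 2")
        if self.image_side % 32:
            raise ValueError("image_side must be divisible by 32")

    def tiny(self) -> "ModelConfig":  # pragma: no cover - convenience
        return replace(self, cg=16, cl=8, reduced_width=16, cond_width=16,
                       local_widths=(8, 16, 24, 32, 32), vit_width=32)


@dataclass
class SegmentationResult:
    """Logits, sigmoid probability map, and the thresholded binary mask."""

    logits: np.ndarray  # (B, 1, H, W)
    prob_map: np.ndarray  # (B, 1, H, W) in [0, 1]
    mask: np.ndarray  # (B, 1, H, W) uint8; 1 exactly where prob >= tau_seg
    tau_seg: float
    prompts: dict = field(default_factory=dict)


class _FusionHead(Module):
    """Concat(global, local) -> two residual blocks -> 1x1 conv -> logits."""

    def __init__(self, channels: int, rng, logit_gain: float, dtype=np.float32):
        self.rb1 = ResidualBlock(channels, rng, dtype=dtype)
        self.rb2 = ResidualBlock(channels, rng, dtype=dtype)
        self.out = Conv2d(channels, 1, 1, rng, zero_init=True, dtype=dtype)
        self.logit_gain = logit_gain

    def forward(self, fg: Tensor, fl: Tensor) -> Tensor:
        if fg.shape[2:] != fl.shape[2:]:
            raise ValueError(
                f"branch spatial shapes differ: {fg.shape[2:]} vs {fl.shape[2:]}")
        fcat = ad.concat([fg, fl], axis=1)
        fused = self.rb2(self.rb1(fcat))
        return ad.mul(self.out(fused), self.logit_gain)


class DualPromptSegModel(Module):
    """Dual-branch, dual-prompt lesion segmenter."""

    def __init__(self, config: ModelConfig, backbone: VisionBackbone, seed: int = 0):
        from .text_embedding import EmbeddingProjector

        self.config = config
        rng = spawn_rng(seed, "model")
        dtype = np.float32
        d = config.cond_width
        self.ec_projector = EmbeddingProjector(config.embed_dim, d, rng, dtype=dtype)
        self.el_projector = EmbeddingProjector(config.embed_dim, d, rng, dtype=dtype)
        n_up = 4 if config.working_stride == 1 else 3
        if config.use_gfe:
            self.global_branch = GlobalBranch(
                backbone, config.layer_set, config.reduced_width, d, config.cg, rng,
                residual_sfa=config.residual_sfa, token_softmax=config.token_softmax,
                n_upsample=n_up, dtype=dtype)
            self.global_stub = None
        else:
            self.global_branch = None
            self.global_stub = Parameter(np.zeros((1, config.cg, 1, 1), dtype=dtype))
        if config.use_lfe:
            self.local_branch = LocalBranch(
                config.image_side, config.local_widths, config.cl, d, rng,
                n_heads=config.local_heads, residual_sfa=config.residual_sfa,
                final_upsample=(config.working_stride == 1), dtype=dtype)
            self.local_stub = None
        else:
            self.local_branch = None
            self.local_stub = Parameter(np.zeros((1, config.cl, 1, 1), dtype=dtype))
        self.head = _FusionHead(config.cg + config.cl, rng, config.logit_gain, dtype)
        if not config.use_sfa:
            self._freeze_conditioning()

    def _freeze_conditioning(self) -> None:
        mods: list[Module] = []
        if self.global_branch is not None:
            mods += [self.global_branch.sfa, self.global_branch.w_mul,
                     self.global_branch.w_add]
        if self.local_branch is not None:
            lb = self.local_branch
            mods += [lb.sfa_enc4, lb.sfa_dec4, lb.sfa_dec3, lb.sfa_dec2, lb.sfa_out]
        mods += [self.ec_projector, self.el_projector]
        for m in mods:
            for _, p in m.named_parameters():
                p.requires_grad = False

    # -- forward --------------------------------------------------------------
    def forward(self, images: np.ndarray, ec: np.ndarray, el: np.ndarray) -> Tensor:
        """Images (B, 3, H, W) + raw prompt embeddings (B, e) -> logits tensor."""
        B = images.shape[0]
        use_sfa = self.config.use_sfa
        h = images.shape[2] // self.config.working_stride
        w = images.shape[3] // self.config.working_stride
        if self.global_branch is not None:
            ec_proj = self.ec_projector(ec)
            fg = self.global_branch(images, ec_proj, use_sfa=use_sfa)
        else:
            fg = ad.add(self.global_stub, np.zeros((B, self.config.cg, h, w), np.float32))
        if self.local_branch is not None:
            el_proj = self.el_projector(el)
            fl = self.local_branch(images, el_proj, use_sfa=use_sfa)
        else:
            fl = ad.add(self.local_stub, np.zeros((B, self.config.cl, h, w), np.float32))
        logits = self.head(fg, fl)
        for _ in range(self.config.working_stride.bit_length() - 1):
            logits = ad.upsample_nearest2(logits)
        return logits

    def predict(self, images: np.ndarray, ec: np.ndarray, el: np.ndarray,
                tau_seg: float = 0.5, prompts: dict | None = None) -> SegmentationResult:
        logits = self.forward(images, ec, el).data
        prob = 1.0 / (1.0 + np.exp(-logits))
        mask = (prob >= tau_seg).astype(np.uint8)
        return SegmentationResult(logits=logits, prob_map=prob, mask=mask,
                                  tau_seg=tau_seg, prompts=prompts or {})


def build_model(config: ModelConfig, seed: int = 0,
                backbone: VisionBackbone | None = None) -> DualPromptSegModel:
    """Construct the model; a seeded frozen toy ViT is the default backbone."""
    if backbone is None:
        backbone = ToyViT(width=config.vit_width, n_layers=config.vit_layers,
                          n_heads=config.vit_heads, seed=seed)
    bad = [j for j in config.layer_set if not 0 <= j <= backbone.n_layers]
    if bad:
        raise ValueError(f"layer_set entries {bad} outside backbone depth")
    return DualPromptSegModel(config, backbone, seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def soft_dice_loss(logits: Tensor, targets: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - soft Dice between sigmoid(logits) and the binary target."""
    probs = ad.sigmoid(logits)
    t = np.asarray(targets, dtype=probs.dtype)
    inter = ad.sum_(ad.mul(probs, t))
    denom = ad.add(ad.sum_(probs), float(t.sum()))
    dice = ad.div(ad.mul(inter, 2.0), ad.add(denom, eps))
    return ad.sub(1.0, dice)


def segmentation_loss(logits: Tensor, targets: np.ndarray,
                      lambda_dice: float = 1.0, lambda_bce: float = 1.0) -> Tensor:
    """Soft-Dice + pixelwise binary cross-entropy (default weights 1 and 1)."""
    loss = ad.mul(soft_dice_loss(logits, targets), lambda_dice)
    return ad.add(loss, ad.mul(ad.bce_with_logits_mean(logits, targets), lambda_bce))


# ---------------------------------------------------------------------------
# two-pass inference
# ---------------------------------------------------------------------------

def predict_two_pass(model: DualPromptSegModel, image: np.ndarray,
                     metadata: LesionMetadata, bins: SizeBins,
                     text_encoder: TextEncoder, run_config: RunConfig | None = None,
                     ) -> SegmentationResult:
    """Mask-free inference: a size-only first pass proposes the location.

    Pass 1 runs with the global prompt stripped of the quadrant clause, the
    resulting probability map is thresholded at the proposal threshold, and
    the largest connected component's centroid supplies the quadrant for the
    full global prompt of pass 2.  With no proposal, pass 2 reuses the pass-1
    prompt.
    """
    rc = run_config or RunConfig(image_side=image.shape[-1])
    from .io_utils import to_model_input

    images = to_model_input(image)
    H, W = image.shape[-2], image.shape[-1]
    size = size_token(metadata.size_value, bins) if metadata.size_value is not None else "medium"
    local_prompt = build_local_prompt(metadata)
    el = encode_batch([local_prompt], text_encoder)

    prompt1 = build_global_prompt(size, None)
    ec1 = encode_batch([prompt1], text_encoder)
    pass1 = model.predict(images, ec1, el, tau_seg=rc.threshold_seg)

    centroid = estimate_location_from_probmap(pass1.prob_map[0, 0], rc.threshold_proposal)
    if centroid is None:
        prompt2 = prompt1
    else:
        quad = quadrant_token(centroid, W, H, metadata.laterality)
        prompt2 = build_global_prompt(size, quad)
    ec2 = encode_batch([prompt2], text_encoder)
    result = model.predict(images, ec2, el, tau_seg=rc.threshold_seg)
    result.prompts = {"pass1_global": prompt1, "pass2_global": prompt2,
                      "local": local_prompt,
                      "proposal_centroid": centroid}
    return result
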