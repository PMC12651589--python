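"""Cross-validation orchestration: fold construction, per-fold prompt-bin
fitting, the training loop (AdamW + cosine schedule), mask-free evaluation,
and size-stratified reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, logger, spawn_rng
from .io_utils import ImageSample, to_model_input
from .layers import AdamW, parameter_checksum
from .metrics import MetricsRecord, bootstrap_ci, compute_metrics, confusion_counts
from .model import (
    DualPromptSegModel,
    ModelConfig,
    build_model,
    predict_two_pass,
    segmentation_loss,
)
from .prompts import (
    SizeBins,
    build_global_prompt,
    build_local_prompt,
    compute_centroid,
    fit_size_bins,
    quadrant_token,
    size_token,
)
from .text_embedding import HashingTextEncoder, TextEncoder, encode_batch

__all__ = [
    "FoldSplit",
    "SizeStratum",
    "SIZE_STRATA",
    "make_folds",
    "cosine_lr",
    "train_fold",
    "evaluate_fold",
    "stratify_by_size",
    "run_cross_validation",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation ids overlap")


@dataclass(frozen=True)
class SizeStratum:
    """Tumor-length interval; lower bound exclusive, upper bound inclusive."""

    label: str
    lower: float
    upper: float

    def contains(self, length: float) -> bool:
        return self.lower < length <= self.upper


#: Length strata in pixels used for the size-stratified analysis.
SIZE_STRATA = (
    SizeStratum("0-110", 0.0, 110.0),
    SizeStratum("111-250", 110.0, 250.0),
    SizeStratum("250+", 250.0, math.inf),
)


def make_folds(ids: list[str], k: int, seed: int,
               independent_splits: bool = False) -> list[FoldSplit]:
    """Seeded K-fold rotation partition (default) of image ids.

    Validation blocks are near-equal (sizes differ by at most one) and
    partition the dataset exactly.  With ``independent_splits`` each fold is
    instead an independent 80/20 draw.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    ids = list(ids)
    if len(ids) < k:
        raise ValueError("fewer ids than folds")
    rng = spawn_rng(seed, "folds")
    if independent_splits:
        splits = []
        for f in range(k):
            perm = list(rng.permutation(ids))
            n_val = round(len(ids) / k)
            splits.append(FoldSplit(f, tuple(perm[n_val:]), tuple(perm[:n_val])))
        return splits
    perm = list(rng.permutation(ids))
    blocks = np.array_split(np.asarray(perm, dtype=object), k)
    splits = []
    for f, block in enumerate(blocks):
        val = tuple(str(x) for x in block)
        train = tuple(x for x in perm if x not in set(val))
        splits.append(FoldSplit(f, train, val))
    return splits


def cosine_lr(t: int, total: int, lr0: float) -> float:
    """Cosine-decayed learning rate: lr0 * (1 + cos(pi t / T)) / 2."""
    return lr0 * (1.0 + math.cos(math.pi * t / total)) / 2.0


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    frozen_checksum_before: str = ""
    frozen_checksum_after: str = ""


def fit_fold_bins(samples_by_id: dict[str, ImageSample], split: FoldSplit) -> SizeBins:
    """Size terciles from the fold's *training* split only (no leakage)."""
    sizes = [samples_by_id[i].metadata.size_value for i in split.train_ids
             if samples_by_id[i].metadata and samples_by_id[i].metadata.size_value]
    return fit_size_bins(sizes, source_fold=split.fold_id)


def _training_prompts(sample: ImageSample, bins: SizeBins) -> tuple[str, str]:
    """Training-time prompts: mask-centroid location plus size tercile."""
    md = sample.metadata
    size = size_token(md.size_value, bins) if md and md.size_value else "medium"
    location = None
    if sample.mask is not None and sample.mask.any():
        H, W = sample.mask.shape
        cent = compute_centroid(sample.mask)
        location = quadrant_token(cent, W, H, md.laterality if md else "unknown")
    return (build_global_prompt(size, location),
            build_local_prompt(md) if md else "breast lesion")


def train_fold(samples_by_id: dict[str, ImageSample], split: FoldSplit,
               run_config: RunConfig, model_config: ModelConfig,
               text_encoder: TextEncoder | None = None,
               ) -> tuple[DualPromptSegModel, TrainingHistory, SizeBins]:
    """Train one fold with AdamW and a cosine schedule.

    Batches are resampled with replacement from the training split (the
    iteration budget exceeds the dataset size).  Frozen components (text
    encoder, vision backbone) are verified unchanged via checksums.
    """
    encoder = text_encoder or HashingTextEncoder(embed_dim=model_config.embed_dim)
    bins = fit_fold_bins(samples_by_id, split)
    model = build_model(model_config, seed=run_config.seed + split.fold_id)

    train_ids = list(split.train_ids)
    images = {}
    masks = {}
    ec_cache = {}
    el_cache = {}
    for i in train_ids:
        s = samples_by_id[i]
        if s.mask is None:
            raise ValueError(f"training sample {i} lacks a mask")
        images[i] = s.image
        masks[i] = s.mask
        gp, lp = _training_prompts(s, bins)
        ec_cache[i] = encode_batch([gp], encoder)[0]
        el_cache[i] = encode_batch([lp], encoder)[0]

    history = TrainingHistory()
    history.frozen_checksum_before = _frozen_state_digest(model, encoder)
    params = model.trainable_parameters()
    optimizer = AdamW(params, lr=run_config.learning_rate,
                      weight_decay=run_config.weight_decay)
    rng = spawn_rng(run_config.seed, "train", split.fold_id)
    T = run_config.iterations
    for t in range(T):
        batch_ids = [train_ids[j] for j in
                     rng.integers(0, len(train_ids), size=run_config.batch_size)]
        x = to_model_input(np.stack([images[i] for i in batch_ids]))
        y = np.stack([masks[i] for i in batch_ids])[:, None].astype(np.float32)
        ec = np.stack([ec_cache[i] for i in batch_ids])
        el = np.stack([el_cache[i] for i in batch_ids])
        logits = model.forward(x, ec, el)
        loss = segmentation_loss(logits, y)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"fold {split.fold_id}: loss became non-finite at iteration {t}")
        model.zero_grad()
        loss.backward()
        optimizer.step(lr=cosine_lr(t, T, run_config.learning_rate))
        history.loss.append(value)
        history.lr.append(cosine_lr(t, T, run_config.learning_rate))
        if t % max(1, T // 10) == 0:
            logger.info("fold %d iter %d/%d loss %.4f", split.fold_id, t, T, value)
    history.frozen_checksum_after = _frozen_state_digest(model, encoder)
    if history.frozen_checksum_before != history.frozen_checksum_after:
        raise RuntimeError("frozen components changed during training")
    return model, history, bins


def _frozen_state_digest(model: DualPromptSegModel, encoder) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(parameter_checksum(model, only_frozen=True).encode())
    if model.global_branch is not None:
        bb = model.global_branch.backbone
        for arr in (bb._wpe, bb._cls):
            h.update(np.ascontiguousarray(arr).tobytes())
        for blk in bb._blocks:
            for v in blk.values():
                if isinstance(v, tuple):
                    for a in v:
                        h.update(np.ascontiguousarray(a).tobytes())
                else:
                    h.update(np.ascontiguousarray(v).tobytes())
    if isinstance(encoder, HashingTextEncoder):
        h.update(np.ascontiguousarray(encoder._proj).tobytes())
    return h.hexdigest()


def evaluate_fold(model: DualPromptSegModel, samples_by_id: dict[str, ImageSample],
                  split: FoldSplit, bins: SizeBins, run_config: RunConfig,
                  text_encoder: TextEncoder | None = None,
                  use_mask_prompts: bool = False) -> list[MetricsRecord]:
    """Score every validation image with the two-pass (mask-free) procedure.

    Validation prompts never see the reference mask; requesting mask-derived
    prompts here raises, as a leakage guard.
    """
    if use_mask_prompts:
        raise ValueError(
            "leakage guard: mask-derived prompts are not allowed in validation")
    encoder = text_encoder or HashingTextEncoder(embed_dim=model.config.embed_dim)
    records = []
    for i in split.val_ids:
        s = samples_by_id[i]
        result = predict_two_pass(model, s.image, s.metadata, bins, encoder, run_config)
        counts = confusion_counts(result.mask[0, 0], s.mask)
        records.append(compute_metrics(counts, image_id=i))
    return records


def stratify_by_size(records: list[MetricsRecord], truth_sizes: dict[str, float],
                     strata: tuple[SizeStratum, ...] = SIZE_STRATA,
                     resamples: int = 2000, seed: int = 0) -> dict[str, dict]:
    """Group per-image metrics by lesion-length stratum; mean and 95% CI per bin.

    Empty strata are omitted from the result rather than raising.
    """
    out: dict[str, dict] = {}
    for stratum in strata:
        sub = [r for r in records if stratum.contains(truth_sizes[r.image_id])]
        if not sub:
            continue
        entry = {"n": len(sub)}
        for name in ("dice", "iou"):
            vals = np.array([getattr(r, name) for r in sub], dtype=float)
            entry[name] = float(vals.mean())
            if vals.size >= 2:
                lo, hi = bootstrap_ci(vals, resamples=resamples, seed=seed)
                entry[f"{name}_ci"] = (lo, hi)
        out[stratum.label] = entry
    return out


def run_cross_validation(samples: list[ImageSample], run_config: RunConfig,
                         model_config: ModelConfig,
                         text_encoder: TextEncoder | None = None,
                         ) -> dict:
    """Train and evaluate all folds; returns per-fold records and histories."""
    samples_by_id = {s.image_id: s for s in samples}
    splits = make_folds(sorted(samples_by_id), run_config.folds, run_config.seed)
    all_records: list[MetricsRecord] = []
    fold_ids: list[int] = []
    histories = {}
    for split in splits:
        model, history, bins = train_fold(samples_by_id, split, run_config,
                                          model_config, text_encoder)
        records = evaluate_fold(model, samples_by_id, split, bins, run_config,
                                text_encoder)
        all_records.extend(records)
        fold_ids.extend([split.fold_id] * len(records))
        histories[split.fold_id] = history
    return {"records": all_records, "fold_ids": fold_ids, "histories": histories,
            "splits": splits}
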