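"""Run configuration, seeding, and logging."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("busseg")

#: Vision-transformer patch size; image sides must be divisible by this.
PATCH_SIZE = 16
#: Local encoder downsampling factor; image sides must be divisible by this.
BACKBONE_STRIDE = 32


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def spawn_rng(seed: int, *tags: object) -> np.random.Generator:
    """Derive an independent, reproducible generator from a base seed and tags."""
    material = [int(seed)] + [
        int.from_bytes(str(t).encode(), "little") % (2**31) for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(material))


@dataclass
class RunConfig:
    """Training/evaluation protocol settings.

    Defaults follow the study protocol: 352x352 inputs, five folds, 1000
    AdamW iterations per fold at batch size 4, initial learning rate 1e-4
    with a cosine schedule, segmentation threshold 0.5 and location-proposal
    threshold 0.30.
    """

    image_side: int = 352
    folds: int = 5
    batch_size: int = 4
    iterations: int = 1000
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    seed: int = 0
    amp_enabled: bool = True
    threshold_seg: float = 0.5
    threshold_proposal: float = 0.30

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_seg < 1.0):
            raise ValueError("threshold_seg must lie in (0, 1)")
        if not (0.0 < self.threshold_proposal < 1.0):
            raise ValueError("threshold_proposal must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for field in ("image_side", "batch_size", "iterations"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.image_side % PATCH_SIZE:
            raise ValueError(
                f"image_side must be divisible by the vision patch size {PATCH_SIZE}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
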