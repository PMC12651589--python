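"""Deterministic construction of the two text prompts from structured metadata.

The *global* prompt verbalizes lesion size (training-split size terciles) and
image-quadrant location (mask centroid during training; a mask-free bootstrap
from a first-pass probability map at validation/test time).  The *local*
prompt verbalizes the BI-RADS appearance attributes: shape, margin, and the
BI-RADS category itself.

All functions here are pure: the same inputs yield byte-identical strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionMetadata",
    "Centroid",
    "SizeBins",
    "PromptPair",
    "compute_centroid",
    "fit_size_bins",
    "size_token",
    "quadrant_token",
    "build_global_prompt",
    "build_local_prompt",
    "build_prompt_pair",
    "estimate_location_from_probmap",
]

SHAPE_VOCAB = ("oval", "round", "irregular")
MARGIN_VOCAB = ("circumscribed", "indistinct", "angular", "microlobulated", "spiculated")
BIRADS_VOCAB = (2, 3, 4, 5)
LATERALITY_VOCAB = ("left", "right", "unknown")

NEUTRAL_LOCAL_PROMPT = "breast lesion"

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class LesionMetadata:
    """Structured clinical attributes of a single lesion.

    ``size_value`` is the lesion length in pixels (major axis of the
    annotation); categorical fields use the BI-RADS lexicon, with ``None``
    as the explicit missing sentinel.
    """

    size_value: float | None = None
    shape: str | None = None
    margin: str | None = None
    birads: int | None = None
    laterality: str | None = "unknown"

    def __post_init__(self) -> None:
        if self.size_value is not None and not self.size_value > 0:
            raise ValueError("size_value must be positive when present")
        if self.shape is not None and self.shape not in SHAPE_VOCAB:
            raise ValueError(f"shape must be one of {SHAPE_VOCAB}")
        if self.margin is not None and self.margin not in MARGIN_VOCAB:
            raise ValueError(f"margin must be one of {MARGIN_VOCAB}")
        if self.birads is not None and self.birads not in BIRADS_VOCAB:
            raise ValueError(f"birads must be one of {BIRADS_VOCAB}")
        if self.laterality is not None and self.laterality not in LATERALITY_VOCAB:
            raise ValueError(f"laterality must be one of {LATERALITY_VOCAB}")


@dataclass(frozen=True)
class Centroid:
    """Continuous 0-based image coordinates: cx = column, cy = row."""

    cx: float
    cy: float


@dataclass(frozen=True)
class SizeBins:
    """Size tercile edges fitted on one fold's training split only."""

    lower_edge: float
    upper_edge: float
    source_fold: int | None = None

    def __post_init__(self) -> None:
        if self.lower_edge > self.upper_edge:
            raise ValueError("lower_edge must not exceed upper_edge")


@dataclass(frozen=True)
class PromptPair:
    global_prompt: str
    local_prompt: str

    def __post_init__(self) -> None:
        if not self.global_prompt or not self.local_prompt:
            raise ValueError("prompts must be non-empty")


class EmptyMaskError(ValueError):
    """Raised when a centroid is requested for a mask with no foreground."""


def compute_centroid(mask: np.ndarray) -> Centroid:
    """Foreground mass centroid from image moments.

    ``Cx = M10 / M00`` and ``Cy = M01 / M00`` where ``M00`` is the foreground
    pixel count and ``M10``/``M01`` are the first-order sums of column/row
    indices.
    """
    mask = np.asarray(mask)
    m00 = float(mask.sum())
    if m00 == 0:
        raise EmptyMaskError("cannot compute the centroid of an empty mask")
    rows, cols = np.nonzero(mask)
    return Centroid(cx=float(cols.sum()) / m00, cy=float(rows.sum()) / m00)


def fit_size_bins(training_sizes, source_fold: int | None = None) -> SizeBins:
    """Tercile edges (1/3 and 2/3 empirical quantiles) of the training sizes."""
    sizes = np.asarray(list(training_sizes), dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 training sizes to fit terciles")
    lo, hi = np.quantile(sizes, [1.0 / 3.0, 2.0 / 3.0])
    return SizeBins(lower_edge=float(lo), upper_edge=float(hi), source_fold=source_fold)


def size_token(size_value: float, bins: SizeBins) -> str:
    """Map a lesion length to small/medium/large; values on an edge are medium."""
    if size_value < bins.lower_edge:
        return "small"
    if size_value > bins.upper_edge:
        return "large"
    return "medium"


def quadrant_token(centroid: Centroid, width: int, height: int,
                   laterality: str | None = "unknown") -> str:
    """Map an image centroid to a breast-quadrant phrase (upper/lower x inner/outer).

    Image halves stand in for anatomical quadrants.  The horizontal half is
    converted to inner/outer using laterality: on a right breast the left
    image half faces outward; on a left breast it faces inward; with unknown
    laterality the left half maps to "inner" by fixed convention.  A centroid
    exactly on a midline maps to upper/inner.
    """
    vertical = "upper" if centroid.cy <= height / 2.0 else "lower"
    if centroid.cx == width / 2.0:  # exact midline ties to "inner"
        horizontal = "inner"
    elif laterality == "right":
        horizontal = "outer" if centroid.cx < width / 2.0 else "inner"
    else:  # "left" or unknown: left image half is the inner side
        horizontal = "inner" if centroid.cx < width / 2.0 else "outer"
    return f"{vertical} {horizontal}"


def build_global_prompt(size: str, location: str | None) -> str:
    """Fixed-template global prompt; the quadrant clause is omitted when the
    location could not be established (empty-mask / no-proposal fallback)."""
    if location is None:
        return f"a {size} lesion"
    return f"a {size} lesion in the {location} quadrant"


def build_local_prompt(metadata: LesionMetadata) -> str:
    """Verbalize shape, margin, and BI-RADS; missing fields are omitted.

    With every field missing the neutral prompt "breast lesion" is returned.
    """
    parts = []
    if metadata.shape is not None:
        parts.append(f"{metadata.shape} shape")
    if metadata.margin is not None:
        parts.append(f"{metadata.margin} margin")
    if metadata.birads is not None:
        parts.append(f"BI-RADS {metadata.birads}")
    return ", ".join(parts) if parts else NEUTRAL_LOCAL_PROMPT


def build_prompt_pair(metadata: LesionMetadata, bins: SizeBins,
                      centroid: Centroid | None, width: int, height: int) -> PromptPair:
    """Assemble both prompts for one image."""
    size = size_token(metadata.size_value, bins) if metadata.size_value is not None else "medium"
    location = None
    if centroid is not None:
        location = quadrant_token(centroid, width, height, metadata.laterality)
    return PromptPair(
        global_prompt=build_global_prompt(size, location),
        local_prompt=build_local_prompt(metadata),
    )


def estimate_location_from_probmap(prob_map: np.ndarray, tau: float = 0.30) -> Centroid | None:
    """Mask-free location bootstrap for validation/test images.

    Threshold the first-pass probability map at ``tau`` (inclusive), label
    8-connected components, keep the largest (ties broken by the smaller
    top-left flattened pixel index), and return its centroid.  Returns
    ``None`` (no proposal) when no pixel reaches the threshold.
    """
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    binary = prob_map >= tau
    if not binary.any():
        return None
    labels, n = ndimage.label(binary, structure=_CONN8)
    flat = labels.ravel()
    sizes = np.bincount(flat)[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        first_idx = [np.flatnonzero(flat == lab)[0] for lab in best]
        chosen = int(best[int(np.argmin(first_idx))])
    else:
        chosen = int(best[0])
    return compute_centroid(labels == chosen)
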