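"""Reading, writing, and resizing image/mask/metadata triplets.

Dataset layout on disk::

    <root>/images/<image_id>.png     8-bit grayscale
    <root>/masks/<image_id>.png      8-bit binary (0 / 255)
    <root>/metadata.csv              image_id, size_px, shape, margin,
                                     birads, laterality

Images are kept in memory as float grids in [0, 1]; masks as {0, 1} uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .config import PATCH_SIZE, logger
from .prompts import LesionMetadata

__all__ = [
    "ImageSample",
    "load_dataset",
    "save_dataset",
    "resize_sample",
    "is_multi_lesion",
    "to_model_input",
]

METADATA_COLUMNS = ["image_id", "size_px", "shape", "margin", "birads", "laterality"]

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class ImageSample:
    """One grayscale ultrasound image with optional mask and metadata."""

    image_id: str
    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray | None = None  # (H, W) uint8 in {0, 1}
    metadata: LesionMetadata | None = None
    extra: dict = field(default_factory=dict)  # e.g. synthetic generation params

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if not np.all(np.isfinite(self.image)):
            raise ValueError(f"{self.image_id}: image contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape:
                raise ValueError(f"{self.image_id}: mask shape differs from image shape")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError(f"{self.image_id}: mask values must be 0/1")
            self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def is_multi_lesion(mask: np.ndarray, min_component_px: int = 25) -> bool:
    """True when the mask holds >=2 8-connected components above a size floor."""
    labels, n = ndimage.label(mask, structure=_CONN8)
    if n < 2:
        return False
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes > min_component_px).sum()) >= 2


def _read_gray(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.float32)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending file
        raise OSError(f"unreadable image file: {path}") from exc
    return arr / 255.0


def _metadata_from_row(row: pd.Series) -> LesionMetadata:
    def _get(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return v

    size = _get("size_px")
    birads = _get("birads")
    return LesionMetadata(
        size_value=float(size) if size is not None else None,
        shape=_get("shape"),
        margin=_get("margin"),
        birads=int(birads) if birads is not None else None,
        laterality=_get("laterality") or "unknown",
    )


def load_dataset(
    images_dir: str | Path,
    metadata_file: str | Path,
    masks_dir: str | Path | None = None,
    side: int | None = None,
    require_masks: bool = True,
    min_component_px: int = 25,
) -> list[ImageSample]:
    """Load all samples listed in a metadata CSV.

    Images with multiple annotated lesions (>=2 sizeable connected mask
    components) are excluded and counted in a log message.  When ``side`` is
    given every retained sample is resized to ``side`` x ``side``.
    """
    images_dir = Path(images_dir)
    metadata_file = Path(metadata_file)
    if masks_dir is None:
        masks_dir = images_dir.parent / "masks"
    masks_dir = Path(masks_dir)

    meta = pd.read_csv(metadata_file, dtype={"image_id": str})
    if meta.empty:
        logger.warning("load_dataset: metadata file %s lists no images", metadata_file)
        return []

    samples: list[ImageSample] = []
    n_multi = 0
    for _, row in meta.iterrows():
        image_id = str(row["image_id"])
        img_path = images_dir / f"{image_id}.png"
        if not img_path.exists():
            raise FileNotFoundError(f"missing image file for id {image_id}: {img_path}")
        image = _read_gray(img_path)
        mask_path = masks_dir / f"{image_id}.png"
        mask = None
        if mask_path.exists():
            mask = (_read_gray(mask_path) > 0.5).astype(np.uint8)
        elif require_masks:
            raise FileNotFoundError(f"missing mask for training sample {image_id}")
        if mask is not None and is_multi_lesion(mask, min_component_px):
            n_multi += 1
            continue
        sample = ImageSample(image_id, image, mask, _metadata_from_row(row))
        if side is not None and sample.shape != (side, side):
            sample = resize_sample(sample, side)
        samples.append(sample)
    if n_multi:
        logger.info("load_dataset: excluded %d multi-lesion image(s)", n_multi)
    return samples


def save_dataset(samples: list[ImageSample], root: str | Path) -> Path:
    """Write images/, masks/ and metadata.csv under ``root``."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img8 = np.clip(np.rint(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(root / "images" / f"{s.image_id}.png")
        if s.mask is not None:
            Image.fromarray((s.mask * 255).astype(np.uint8), mode="L").save(
                root / "masks" / f"{s.image_id}.png")
        md = s.metadata
        rows.append({
            "image_id": s.image_id,
            "size_px": md.size_value if md else None,
            "shape": md.shape if md else None,
            "margin": md.margin if md else None,
            "birads": md.birads if md else None,
            "laterality": md.laterality if md else None,
        })
    path = root / "metadata.csv"
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)
    return path


def resize_sample(sample: ImageSample, side: int) -> ImageSample:
    """Resize to ``side`` x ``side``: bilinear image, nearest-neighbour mask.

    ``side`` must be divisible by the vision patch size so the transformer
    token grid is integral.
    """
    if side % PATCH_SIZE:
        raise ValueError(
            f"target side {side} is not divisible by the vision patch size "
            f"{PATCH_SIZE}; the token grid would not be integral")
    if sample.shape == (side, side):
        return sample
    image = _sk_resize(sample.image, (side, side), order=1, mode="reflect",
                       anti_aliasing=False, preserve_range=True).astype(np.float32)
    mask = None
    if sample.mask is not None:
        mask = _sk_resize(sample.mask.astype(float), (side, side), order=0,
                          mode="edge", anti_aliasing=False, preserve_range=True)
        mask = (mask > 0.5).astype(np.uint8)
    return ImageSample(sample.image_id, image, mask, sample.metadata, dict(sample.extra))


def to_model_input(images: np.ndarray) -> np.ndarray:
    """Stack grayscale images (B, H, W) into 3-channel (B, 3, H, W) float32."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    return np.repeat(images[:, None, :, :], 3, axis=1)
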