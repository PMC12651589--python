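"""Speckle-textured ultrasound-like phantoms with one hypoechoic lesion.

Each phantom is a multiplicative-speckle background (smoothed log-normal
texture over a smooth tissue gradient) containing a single star-convex
hypoechoic region whose boundary is a low-order harmonic perturbation of an
ellipse.  The binary mask is the exact lesion support before edge smoothing,
and metadata (size, shape, margin, BI-RADS surrogate, laterality) is derived
deterministically from the generation parameters so that the prompt pipeline
can be exercised end-to-end with no external data.

This generator aims at controllable difficulty (size, contrast, boundary
irregularity, margin blur), not at acoustic realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import spawn_rng
from .io_utils import ImageSample
from .prompts import Centroid, LesionMetadata, quadrant_token

__all__ = ["SyntheticSpec", "generate_dataset", "oracle_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.

    ``lesion_length_range`` is the major-axis length in pixels;
    ``contrast_range`` the relative intensity drop inside the lesion;
    ``boundary_irregularity`` the maximum radial harmonic amplitude (per-image
    amplitudes are drawn from [0, value]); ``margin_blur`` the maximum edge
    smoothing scale in pixels; ``speckle_scale`` the log-amplitude of the
    multiplicative texture.
    """

    n_images: int = 200
    side: int = 352
    lesion_length_range: tuple[float, float] = (40.0, 260.0)
    contrast_range: tuple[float, float] = (0.30, 0.60)
    boundary_irregularity: float = 0.30
    margin_blur: float = 2.0
    speckle_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_length_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_length_range must be positive and ordered")
        clo, chi = self.contrast_range
        if not (0 < clo <= chi < 1):
            raise ValueError("contrast_range must lie in (0, 1)")
        if self.n_images <= 0 or self.side <= 0:
            raise ValueError("n_images and side must be positive")
        # the most irregular lesion must still fit inside the image
        max_radius = hi / 2.0 * (1.0 + self.boundary_irregularity)
        if 2 * max_radius >= self.side - 4:
            raise ValueError("largest lesion does not fit inside the image")


_SHAPE_IRREGULAR_THRESHOLD = 0.15
_MARGIN_BLUR_THRESHOLD = 1.0


def _lesion_mask(side: int, center: tuple[float, float], length: float,
                 axis_ratio: float, rotation: float, amplitude: float,
                 harmonics: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Star-convex region: r(theta) = r_ellipse(theta) * (1 + a * sum cos)."""
    cy, cx = center
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)
    a = length / 2.0
    b = a * axis_ratio
    tr = theta - rotation
    r_ell = a * b / np.sqrt((b * np.cos(tr)) ** 2 + (a * np.sin(tr)) ** 2)
    pert = np.zeros_like(theta)
    for k, phi in zip(harmonics, phases):
        pert += np.cos(k * theta + phi)
    pert /= max(1, len(harmonics))
    radius = r_ell * (1.0 + amplitude * pert)
    return (rr <= radius).astype(np.uint8)


def _analytic_major_axis(length: float, axis_ratio: float, rotation: float,
                         amplitude: float, harmonics: np.ndarray,
                         phases: np.ndarray) -> float:
    """Maximum caliper diameter of the radial boundary (analytic feret)."""
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    a = length / 2.0
    b = a * axis_ratio
    tr = theta - rotation
    r_ell = a * b / np.sqrt((b * np.cos(tr)) ** 2 + (a * np.sin(tr)) ** 2)
    pert = np.zeros_like(theta)
    for k, phi in zip(harmonics, phases):
        pert += np.cos(k * theta + phi)
    pert /= max(1, len(harmonics))
    r = r_ell * (1.0 + amplitude * pert)
    pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def generate_dataset(spec: SyntheticSpec) -> list[ImageSample]:
    """Generate phantoms with masks and metadata; byte-identical per seed."""
    samples: list[ImageSample] = []
    for idx in range(spec.n_images):
        rng = spawn_rng(spec.seed, "synth", idx)
        side = spec.side
        length = float(rng.uniform(*spec.lesion_length_range))
        amplitude = float(rng.uniform(0.0, spec.boundary_irregularity))
        axis_ratio = float(rng.uniform(0.55, 0.9))
        rotation = float(rng.uniform(0.0, np.pi))
        blur = float(rng.uniform(0.2, max(0.2, spec.margin_blur)))
        contrast = float(rng.uniform(*spec.contrast_range))
        margin = length / 2.0 * (1.0 + amplitude) + 3.0
        cx = float(rng.uniform(margin, side - margin))
        cy = float(rng.uniform(margin, side - margin))
        harmonics = np.array([2, 3, 4, 5])
        phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)

        mask = _lesion_mask(side, (cy, cx), length, axis_ratio, rotation,
                            amplitude, harmonics, phases)
        major_axis = _analytic_major_axis(length, axis_ratio, rotation,
                                          amplitude, harmonics, phases)

        # smooth tissue gradient, slightly darker with depth
        depth = np.linspace(0.0, 1.0, side)[:, None]
        tissue = 0.62 - 0.12 * depth + 0.04 * np.cos(
            np.linspace(0, 2 * np.pi, side))[None, :]
        alpha = ndimage.gaussian_filter(mask.astype(np.float64), blur)
        tissue = tissue * (1.0 - contrast * alpha)
        speckle = np.exp(spec.speckle_scale *
                         ndimage.gaussian_filter(rng.standard_normal((side, side)), 1.2))
        speckle /= speckle.mean()
        image = np.clip(tissue * speckle, 0.0, 1.0)
        image = np.rint(image * 255.0) / 255.0  # quantize: exact save/load round-trip

        shape = "oval" if amplitude < _SHAPE_IRREGULAR_THRESHOLD else "irregular"
        margin_term = ("circumscribed" if blur < _MARGIN_BLUR_THRESHOLD
                       else "microlobulated")
        birads = 3 if (shape == "oval" and margin_term == "circumscribed") else 4
        laterality = ("left", "right", "unknown")[int(rng.integers(0, 3))]
        metadata = LesionMetadata(size_value=major_axis, shape=shape,
                                  margin=margin_term, birads=birads,
                                  laterality=laterality)
        sample = ImageSample(
            image_id=f"synth_{idx:04d}", image=image.astype(np.float32),
            mask=mask, metadata=metadata,
            extra={"center": (cx, cy), "length": major_axis,
                   "length_param": length, "amplitude": amplitude,
                   "axis_ratio": axis_ratio, "rotation": rotation,
                   "contrast": contrast, "blur": blur})
        samples.append(sample)
    return samples


def oracle_truth(sample: ImageSample) -> tuple[Centroid, float, str]:
    """Analytic centroid, length, and quadrant from the generation parameters.

    Independent of the stored mask; used to cross-check the prompt pipeline.
    """
    if "center" not in sample.extra:
        raise ValueError("sample does not carry generation parameters")
    cx, cy = sample.extra["center"]
    centroid = Centroid(cx=float(cx), cy=float(cy))
    H, W = sample.image.shape
    laterality = sample.metadata.laterality if sample.metadata else "unknown"
    quadrant = quadrant_token(centroid, W, H, laterality)
    return centroid, float(sample.extra["length"]), quadrant
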