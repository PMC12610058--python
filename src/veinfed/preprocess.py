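"""Gradient-based enhancement and edge-intensity quality scoring.

Vein boundaries are the most identity-bearing structure in a finger-vein
image, so each client sharpens them before embedding: a Sobel gradient
image is computed, large (noise-dominated) responses above a threshold T
are suppressed, and the remainder is added back onto the original image.
The total retained gradient mass of an image — its *edge intensity* — is
a cheap proxy for image quality; averaged per class, min-max normalized
within a client and pushed through a logistic curve, it becomes a 0-100
quality score that later modulates the classification margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import correlate

from .synthetic import ClientDataset, VeinImage

__all__ = [
    "SOBEL_KERNEL",
    "SobelConfig",
    "QualityIndicatorParams",
    "ClassQualityRecord",
    "sobel_gradient",
    "enhance",
    "enhance_image",
    "edge_intensity",
    "class_edge_intensities",
    "normalize_edge_intensities",
    "quality_score",
    "batch_quality_indicator",
    "compute_quality_records",
    "quality_records_to_frame",
]

# vertical-finger stencil; the horizontal case uses its transpose
SOBEL_KERNEL = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)


@dataclass(frozen=True)
class SobelConfig:
    """Orientation-aware Sobel configuration.

    ``gradient_threshold`` T suppresses responses above it: pixels whose
    raw |G * I| exceeds T are zeroed (the convention treats very strong
    responses as artifacts rather than vein edges).
    """

    orientation: str = "horizontal"
    gradient_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.gradient_threshold <= 0:
            raise ValueError("gradient_threshold must be positive")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")

    @property
    def kernel(self) -> np.ndarray:
        if self.orientation == "vertical":
            return SOBEL_KERNEL
        return SOBEL_KERNEL.T


@dataclass(frozen=True)
class QualityIndicatorParams:
    """Logistic steepness u and batch z-score clip scale h."""

    steepness: float = 10.0
    clip_scale: float = 0.33

    def __post_init__(self) -> None:
        if self.steepness <= 0 or self.clip_scale <= 0:
            raise ValueError("steepness and clip_scale must be positive")


@dataclass
class ClassQualityRecord:
    class_label: int
    edge_intensity: float  # class mean b
    normalized: float = float("nan")  # b' in [0, 1]
    quality: float = float("nan")  # Q in (0, 100)


def _as_float_image(image: VeinImage | np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, VeinImage) else image
    return np.asarray(pixels, dtype=float)


def sobel_gradient(
    image: VeinImage | np.ndarray, config: SobelConfig = SobelConfig()
) -> np.ndarray:
    """Thresholded absolute Sobel response, same shape as the input.

    Borders are replicate-padded.  Every output pixel lies in [0, T].
    """
    pixels = _as_float_image(image)
    if pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for a Sobel stencil")
    raw = np.abs(correlate(pixels, config.kernel, mode="nearest"))
    return np.where(raw > config.gradient_threshold, 0.0, raw)


def enhance(
    image: VeinImage | np.ndarray, gradient: np.ndarray
) -> np.ndarray:
    """I' = clip(I + Ig, 0, 255): add edge mass back onto the image."""
    pixels = _as_float_image(image)
    gradient = np.asarray(gradient, dtype=float)
    if pixels.shape != gradient.shape:
        raise ValueError(
            f"shape mismatch: image {pixels.shape} vs gradient {gradient.shape}"
        )
    return np.clip(pixels + gradient, 0.0, 255.0)


def enhance_image(
    image: VeinImage, config: SobelConfig = SobelConfig()
) -> tuple[np.ndarray, float]:
    """Convenience: one pass returning (enhanced pixels, edge intensity b)."""
    grad = sobel_gradient(image, config)
    return enhance(image, grad), edge_intensity(grad)


def edge_intensity(gradient: np.ndarray) -> float:
    """b = sum of all (thresholded) gradient pixels."""
    return float(np.sum(gradient))


def class_edge_intensities(
    dataset: ClientDataset | list[VeinImage],
    config: SobelConfig = SobelConfig(),
) -> dict[int, float]:
    """Per-class mean edge intensity over the client's samples."""
    images = dataset.images if isinstance(dataset, ClientDataset) else dataset
    per_class: dict[int, list[float]] = {}
    for im in images:
        per_class.setdefault(im.class_label, []).append(
            edge_intensity(sobel_gradient(im, config))
        )
    if not per_class:
        raise ValueError("dataset has no samples")
    return {label: float(np.mean(bs)) for label, bs in sorted(per_class.items())}


def normalize_edge_intensities(class_b: dict[int, float]) -> dict[int, float]:
    """Min-max normalize to [0, 1]; degenerate spread maps everything to 0.5.

    The 0.5 convention makes the downstream quality score exactly 50,
    which in turn reduces the adaptive margin to the fixed-margin case.
    """
    if not class_b:
        raise ValueError("empty edge-intensity set")
    values = np.array(list(class_b.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return {label: 0.5 for label in class_b}
    return {label: float((b - lo) / (hi - lo)) for label, b in class_b.items()}


def quality_score(b_prime: float | np.ndarray, steepness: float = 10.0) -> float | np.ndarray:
    """Q = 100 / (1 + exp(-u (b' - 0.5))), a logistic map of [0,1] into (0,100)."""
    b_prime = np.asarray(b_prime, dtype=float)
    q = 100.0 / (1.0 + np.exp(-steepness * (b_prime - 0.5)))
    return float(q) if q.ndim == 0 else q


def batch_quality_indicator(
    q_values: np.ndarray,
    params: QualityIndicatorParams = QualityIndicatorParams(),
) -> np.ndarray:
    """Within-batch standardized quality, clipped to [-1, 1].

    Uses the population standard deviation of the batch's Q values.  A
    batch of one sample, or a batch with zero spread, yields all zeros
    (the neutral indicator that recovers the fixed margin).
    """
    q = np.asarray(q_values, dtype=float)
    if q.size < 1:
        raise ValueError("batch must contain at least one sample")
    sigma = float(np.std(q))
    if q.size == 1 or sigma == 0.0:
        return np.zeros_like(q)
    z = (q - q.mean()) / (sigma * params.clip_scale)
    return np.clip(z, -1.0, 1.0)


def compute_quality_records(
    dataset: ClientDataset | list[VeinImage],
    sobel: SobelConfig = SobelConfig(),
    params: QualityIndicatorParams = QualityIndicatorParams(),
) -> dict[int, ClassQualityRecord]:
    """Full per-class quality pass for one client (run once before training)."""
    class_b = class_edge_intensities(dataset, sobel)
    b_prime = normalize_edge_intensities(class_b)
    return {
        label: ClassQualityRecord(
            class_label=label,
            edge_intensity=class_b[label],
            normalized=b_prime[label],
            quality=float(quality_score(b_prime[label], params.steepness)),
        )
        for label in class_b
    }


def quality_records_to_frame(
    records: dict[int, ClassQualityRecord]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class_label": r.class_label,
                "b": r.edge_intensity,
                "b_prime": r.normalized,
                "Q": r.quality,
            }
            for r in records.values()
        ]
    )
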