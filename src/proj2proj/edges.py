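"""High-frequency loss weighting from the label's Sobel gradient map.

Projection images are dominated by homogeneous regions; a pixel-uniform loss
lets the low-frequency bulk overwhelm the error on edges, which carry most of
the clinically relevant information in fluoroscopy.  The weight map E_L is the
Sobel gradient magnitude of the label projection, normalized to [0, 1],
thresholded so that pixels with low likelihood of belonging to an edge get a
small constant floor weight, and bilinearly resampled to whatever resolution a
loss term map has.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projector import ProjectionImage

__all__ = ["EdgeWeightMap", "sobel_gradient", "make_weight_map", "resample_weights", "bilinear_resize"]


@dataclass
class EdgeWeightMap:
    """Per-pixel loss weights in [floor, 1] derived from a label gradient."""

    weights: np.ndarray
    threshold: float
    floor: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValueError("weight map must be 2D")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if not (0.0 <= self.floor < 1.0):
            raise ValueError("floor must be in [0, 1)")


def sobel_gradient(image: np.ndarray) -> np.ndarray:
    """Normalized Sobel gradient magnitude of a 2D image.

    Classical 3x3 Sobel kernels with edge-replicating border handling; the
    magnitude sqrt(gx^2 + gy^2) is divided by its maximum so the result lives
    on a 0-to-1 data range (an all-constant image maps to all zeros).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be 2D and at least 3x3")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    gx = ndimage.sobel(image, axis=0, mode="nearest")
    gy = ndimage.sobel(image, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak == 0.0:
        return np.zeros_like(mag)
    return mag / peak


def make_weight_map(
    label: ProjectionImage | np.ndarray,
    threshold: float = 0.4,
    floor: float = 0.1,
    binarize: bool = False,
) -> EdgeWeightMap:
    """Build the edge weight map E_L of a label projection.

    Pixels whose normalized gradient magnitude is below ``threshold`` receive
    the constant ``floor`` weight (attenuating homogeneous regions while
    keeping some gradient flow; ``floor=0`` discards them outright).  Pixels
    at or above the threshold keep their gradient magnitude — interpreted as
    the likelihood of belonging to an edge — unless ``binarize`` forces them
    to 1.
    """
    pixels = label.pixels if isinstance(label, ProjectionImage) else np.asarray(label)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    if not (0.0 <= floor < 1.0):
        raise ValueError("floor must be in [0, 1)")
    grad = sobel_gradient(pixels)
    on = grad >= threshold if threshold > 0 else np.ones_like(grad, dtype=bool)
    kept = np.ones_like(grad) if binarize else grad
    weights = np.where(on, kept, floor)
    return EdgeWeightMap(weights, threshold, floor)


def bilinear_resize(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling with pixel-center alignment and edge clamping."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    th, tw = target_shape
    if th < 1 or tw < 1:
        raise ValueError("target_shape must be positive")
    if (th, tw) == (h, w):
        return image.copy()
    rr = (np.arange(th) + 0.5) * h / th - 0.5
    cc = (np.arange(tw) + 0.5) * w / tw - 0.5
    rr = np.clip(rr, 0, h - 1)
    cc = np.clip(cc, 0, w - 1)
    r, c = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(image, [r.ravel(), c.ravel()], order=1, mode="nearest").reshape(th, tw)


def resample_weights(weight_map: EdgeWeightMap, target_shape: tuple[int, int]) -> EdgeWeightMap:
    """Bilinearly resample a weight map (e.g. down to a patch-score or feature
    map resolution), clipping back into [floor, 1]."""
    resized = bilinear_resize(weight_map.weights, target_shape)
    resized = np.clip(resized, weight_map.floor, 1.0)
    return EdgeWeightMap(resized, weight_map.threshold, weight_map.floor)
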