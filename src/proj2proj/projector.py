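"""Cone-beam forward projector: the discretized X-ray transform.

Each detector pixel receives the line integral of the volume along the ray
from the source through that pixel,

    p = integral f(x0 + t * theta) dt,

discretized by midpoint sampling at a fixed step (rectangle rule scaled by the
step length) with trilinear interpolation of the voxel grid.  Samples outside
the volume contribute zero, matching an air background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import ConeBeamGeometry, Volume, detector_pixel_positions

__all__ = ["ProjectionImage", "ProjectionPair", "project", "project_pair"]


@dataclass
class ProjectionImage:
    """A single 2D projection with its view angles and modality tag."""

    pixels: np.ndarray
    view: tuple[float, float]
    modality_tag: str  # {"mr", "xray", "generated"}

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("projection pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection pixels must be finite")
        if self.modality_tag not in ("mr", "xray", "generated"):
            raise ValueError(f"unknown modality tag {self.modality_tag!r}")


@dataclass
class ProjectionPair:
    """Geometrically matched MR-like input I and X-ray-like label L."""

    mr: ProjectionImage
    xray: ProjectionImage

    def __post_init__(self) -> None:
        if self.mr.pixels.shape != self.xray.pixels.shape:
            raise ValueError("paired projections must share shape")
        if self.mr.view != self.xray.view:
            raise ValueError("paired projections must share the view")


def _ray_box_range(src, dirs, lo, hi):
    """Slab intersection of rays with an axis-aligned box.

    ``dirs`` has shape (..., 3).  Returns (t_near, t_far) arrays clipped so
    that t_near <= t_far; rays that miss get t_near == t_far.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
    t0 = (lo[None, None, :] - src[None, None, :]) * inv
    t1 = (hi[None, None, :] - src[None, None, :]) * inv
    # Where a direction component is ~0, the slab constrains nothing if the
    # source lies inside that slab, everything otherwise.
    para = np.abs(dirs) < 1e-12
    inside = (src >= lo) & (src <= hi)
    tmin = np.where(para, np.where(inside, -np.inf, np.inf), np.minimum(t0, t1))
    tmax = np.where(para, np.where(inside, np.inf, -np.inf), np.maximum(t0, t1))
    t_near = np.max(tmin, axis=-1)
    t_far = np.min(tmax, axis=-1)
    t_near = np.maximum(t_near, 0.0)
    t_far = np.maximum(t_far, t_near)
    return t_near, t_far


def project(
    volume: Volume,
    geometry: ConeBeamGeometry,
    view: tuple[float, float],
    step_mm: float | None = None,
    modality_tag: str = "xray",
) -> ProjectionImage:
    """Forward-project one view of a volume.

    Parameters
    ----------
    step_mm:
        Sampling step along each ray; defaults to half the smallest voxel
        spacing.  The integral is the sum of midpoint samples times the step.
    """
    if step_mm is None:
        step_mm = float(np.min(volume.spacing_mm)) / 2.0
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")

    lo, hi = volume.bounding_box()
    src, pix = detector_pixel_positions(geometry, view)
    if np.all(src >= lo) and np.all(src <= hi):
        raise ValueError("degenerate geometry: source lies inside the volume support")

    dirs = pix - src[None, None, :]
    norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = dirs / norms

    t_near, t_far = _ray_box_range(src, dirs, lo, hi)
    t_len = float(np.max(t_far - t_near))
    rows, cols = geometry.detector_shape
    out = np.zeros((rows, cols), dtype=np.float64)
    n_steps = int(np.ceil(t_len / step_mm))
    if n_steps > 0:
        k = (np.arange(n_steps) + 0.5) * step_mm
        # Row blocks cap the sample-coordinate buffer at ~64 MB.
        block = max(1, int(64e6 / (cols * n_steps * 3 * 8)))
        for r0 in range(0, rows, block):
            r1 = min(rows, r0 + block)
            t = t_near[r0:r1, :, None] + k[None, None, :]
            valid = t < t_far[r0:r1, :, None]
            pts = src[None, None, None, :] + t[..., None] * dirs[r0:r1, :, None, :]
            idx = (pts - volume.origin_mm) / volume.spacing_mm
            samp = map_coordinates(
                volume.values,
                [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
                order=1,
                mode="constant",
                cval=0.0,
            ).reshape(r1 - r0, cols, n_steps)
            out[r0:r1] = np.sum(samp * valid, axis=-1) * step_mm
    return ProjectionImage(out, view, modality_tag)


def project_pair(
    volume_mr: Volume,
    volume_xray: Volume,
    geometry: ConeBeamGeometry,
    view: tuple[float, float],
    step_mm: float | None = None,
) -> ProjectionPair:
    """Project two co-registered volumes with the identical ray set."""
    if not volume_mr.same_grid(volume_xray):
        raise ValueError("paired volumes must share grid shape, spacing and origin")
    mr = project(volume_mr, geometry, view, step_mm, modality_tag="mr")
    xr = project(volume_xray, geometry, view, step_mm, modality_tag="xray")
    return ProjectionPair(mr, xr)
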