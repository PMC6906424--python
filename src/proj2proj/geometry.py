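"""Cone-beam acquisition geometry: volumes, view trajectories and rays.

World coordinates are right-handed, in millimetres, with the isocenter at the
origin.  A view is an ``(azimuth_deg, inclination_deg)`` pair: the azimuth
rotates the source in the transversal (x-y) plane with 0 deg along +y, and the
inclination tilts the source out of that plane towards +z.  This is a
simulator-local convention; no claim of clinical RAO/LAO semantics is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "ConeBeamGeometry",
    "Ray",
    "make_trajectory",
    "ray_for_pixel",
    "view_frame",
]


@dataclass
class Volume:
    """A 3D scalar voxel grid with physical spacing.

    ``values[i, j, k]`` lives at world position ``origin + (i, j, k) * spacing``
    (voxel centers); array axes are aligned with the world x, y, z axes.

    Parameters
    ----------
    values:
        3D array of scalars (attenuation per mm for X-ray-like volumes,
        arbitrary intensity units for MR-like volumes).
    spacing_mm:
        Physical size of one voxel along each axis, strictly positive.
    origin_mm:
        World position of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError("all spacing components must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @classmethod
    def centered(cls, values: np.ndarray, spacing_mm) -> "Volume":
        """Create a volume whose center coincides with the isocenter."""
        values = np.asarray(values, dtype=np.float64)
        spacing = np.asarray(spacing_mm, dtype=np.float64).reshape(3)
        origin = -(np.array(values.shape) - 1) * spacing / 2.0
        return cls(values, spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space axis-aligned bounding box of the voxel support
        (half a voxel beyond the outermost voxel centers)."""
        lo = self.origin_mm - self.spacing_mm / 2.0
        hi = self.origin_mm + (np.array(self.shape) - 0.5) * self.spacing_mm
        return lo, hi

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class ConeBeamGeometry:
    """Source/detector configuration of a C-arm-like cone-beam system.

    Defaults emulate a clinical C-arm: magnification ~2 (source-isocenter
    600 mm, source-detector 1200 mm) with a flat-panel detector.
    """

    source_to_isocenter_mm: float = 600.0
    source_to_detector_mm: float = 1200.0
    detector_shape: tuple[int, int] = (256, 256)
    detector_spacing_mm: tuple[float, float] = (1.2, 1.2)
    views: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source_to_isocenter_mm <= 0:
            raise ValueError("source_to_isocenter_mm must be positive")
        if self.source_to_detector_mm <= self.source_to_isocenter_mm:
            raise ValueError("source_to_detector_mm must exceed source_to_isocenter_mm")
        rows, cols = self.detector_shape
        if rows < 1 or cols < 1:
            raise ValueError("detector_shape components must be positive")
        if any(s <= 0 for s in self.detector_spacing_mm):
            raise ValueError("detector_spacing_mm components must be positive")
        for az, inc in self.views:
            _check_view(az, inc)

    def to_dict(self) -> dict:
        return {
            "source_to_isocenter_mm": self.source_to_isocenter_mm,
            "source_to_detector_mm": self.source_to_detector_mm,
            "detector_shape": list(self.detector_shape),
            "detector_spacing_mm": list(self.detector_spacing_mm),
            "views": [list(v) for v in self.views],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConeBeamGeometry":
        return cls(
            source_to_isocenter_mm=d["source_to_isocenter_mm"],
            source_to_detector_mm=d["source_to_detector_mm"],
            detector_shape=tuple(d["detector_shape"]),
            detector_spacing_mm=tuple(d["detector_spacing_mm"]),
            views=[tuple(v) for v in d.get("views", [])],
        )


@dataclass
class Ray:
    """A half-line ``x0 + t * theta`` along which the line integral is taken."""

    x0: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.float64).reshape(3)
        self.theta = np.asarray(self.theta, dtype=np.float64).reshape(3)
        if abs(np.linalg.norm(self.theta) - 1.0) > 1e-9:
            raise ValueError("ray direction must be a unit vector")


def _check_view(azimuth_deg: float, inclination_deg: float) -> None:
    if not (0.0 <= azimuth_deg < 360.0):
        raise ValueError(f"azimuth must be in [0, 360), got {azimuth_deg}")
    if not (-90.0 <= inclination_deg <= 90.0):
        raise ValueError(f"inclination must be in [-90, 90], got {inclination_deg}")


def make_trajectory(
    n_views: int,
    mode: str,
    inclination_range_deg: tuple[float, float] = (-30.0, 30.0),
) -> list[tuple[float, float]]:
    """Return a deterministic list of ``(azimuth_deg, inclination_deg)`` views.

    ``training_sphere`` distributes views equiangularly along both the azimuth
    and the inclination angle on a near-square grid: the grid (azimuth count x
    inclination count) is the smallest such grid with at least ``n_views``
    cells, enumerated row-major and truncated to ``n_views``.  ``test_transversal``
    is a full 360 deg rotation in the transversal plane (inclination 0),
    the common clinical acquisition orbit.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if mode == "test_transversal":
        return [(360.0 * k / n_views, 0.0) for k in range(n_views)]
    if mode != "training_sphere":
        raise ValueError(f"unknown trajectory mode: {mode!r}")

    n_inc = max(1, int(math.floor(math.sqrt(n_views))))
    n_az = math.ceil(n_views / n_inc)
    lo, hi = inclination_range_deg
    if n_inc == 1:
        incs = [0.5 * (lo + hi)]
    else:
        incs = [lo + (hi - lo) * i / (n_inc - 1) for i in range(n_inc)]
    azs = [360.0 * j / n_az for j in range(n_az)]
    views = [(az, inc) for inc in incs for az in azs]
    return views[:n_views]


def view_frame(view: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame of a view: (source direction u, detector column axis,
    detector row axis).  The source sits at ``+SID * u``; the detector plane is
    orthogonal to ``u`` on the far side of the isocenter."""
    az, inc = view
    a = math.radians(az)
    b = math.radians(inc)
    u = np.array([math.cos(b) * math.sin(a), math.cos(b) * math.cos(a), math.sin(b)])
    up = np.array([0.0, 0.0, 1.0])
    ecol = np.cross(up, u)
    n = np.linalg.norm(ecol)
    if n < 1e-9:  # source on the z axis: transversal col axis by azimuth
        ecol = np.array([math.cos(a), -math.sin(a), 0.0])
    else:
        ecol = ecol / n
    erow = np.cross(u, ecol)
    return u, ecol, erow


def detector_pixel_positions(
    geometry: ConeBeamGeometry, view: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Source position and world coordinates of every detector pixel center.

    Returns ``(source (3,), pixels (rows, cols, 3))``.
    """
    _check_view(*view)
    u, ecol, erow = view_frame(view)
    src = geometry.source_to_isocenter_mm * u
    det_center = -(geometry.source_to_detector_mm - geometry.source_to_isocenter_mm) * u
    rows, cols = geometry.detector_shape
    pr, pc = geometry.detector_spacing_mm
    r = (np.arange(rows) - (rows - 1) / 2.0) * pr
    c = (np.arange(cols) - (cols - 1) / 2.0) * pc
    pix = (
        det_center[None, None, :]
        + r[:, None, None] * erow[None, None, :]
        + c[None, :, None] * ecol[None, None, :]
    )
    return src, pix


def ray_for_pixel(
    geometry: ConeBeamGeometry,
    view: tuple[float, float],
    pixel: tuple[int, int],
) -> Ray:
    """The ray from the rotated source through the center of one detector pixel."""
    row, col = pixel
    rows, cols = geometry.detector_shape
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"pixel {pixel} outside detector shape {geometry.detector_shape}")
    src, pix = detector_pixel_positions(geometry, view)
    d = pix[row, col] - src
    return Ray(src, d / np.linalg.norm(d))
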