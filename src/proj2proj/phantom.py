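"""Paired digital head-like phantoms with MR/X-ray signal ambiguity.

Real paired MR and X-ray projection data are clinical and rarely shareable, so
this module generates material-label phantoms (an ellipsoidal bone "skull"
shell around soft tissue, with randomly placed inner bone structures and
vessel-like tubes) and renders them into two co-registered volumes:

* MR-like: soft tissue and vessels give signal, bone and air give (almost)
  none — so bone and air are indistinguishable by intensity, the ambiguity
  that makes the translation problem ill-posed;
* X-ray-like: attenuation per mm, dominated by bone.

Vessels are rendered bright in MR, emulating flow-sensitive (time-of-flight)
angiography only in that abstract sense.  All shape distributions and mapping
constants are package choices; nothing here claims anatomical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import ConeBeamGeometry, Volume, make_trajectory
from .projector import project_pair
from . import proj_io

AIR, SOFT, BONE, VESSEL = 0, 1, 2, 3
MATERIAL_NAMES = {AIR: "air", SOFT: "soft", BONE: "bone", VESSEL: "vessel"}

__all__ = [
    "AIR",
    "SOFT",
    "BONE",
    "VESSEL",
    "MaterialPhantom",
    "ModalityMapping",
    "make_phantom",
    "render_pair",
    "make_dataset",
]


@dataclass
class MaterialPhantom:
    """A voxel grid of material codes plus the seed that produced it."""

    labels: np.ndarray
    spacing_mm: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        known = set(MATERIAL_NAMES)
        present = set(np.unique(self.labels).tolist())
        if not present <= known:
            raise ValueError(f"unknown material codes: {present - known}")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class ModalityMapping:
    """Per-material (mr_intensity, xray_attenuation_per_mm) lookup.

    Defaults keep bone nearly signal-free in MR (<= 5% of soft tissue) while
    dominant in X-ray attenuation, and air at exactly zero in both.
    """

    table: dict = field(
        default_factory=lambda: {
            AIR: (0.0, 0.0),
            SOFT: (1.0, 0.019),
            BONE: (0.03, 0.060),
            VESSEL: (1.8, 0.025),
        }
    )

    def __post_init__(self) -> None:
        mr_air, mu_air = self.table.get(AIR, (None, None))
        if mr_air != 0.0 or mu_air != 0.0:
            raise ValueError("air must map to zero in both modalities")
        if BONE in self.table and SOFT in self.table:
            if self.table[BONE][0] > 0.05 * self.table[SOFT][0]:
                raise ValueError("bone MR intensity must be <= 5% of soft tissue")
            if self.table[BONE][1] <= self.table[SOFT][1]:
                raise ValueError("bone X-ray attenuation must exceed soft tissue")

    @classmethod
    def from_yaml(cls, path) -> "ModalityMapping":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        name_to_code = {v: k for k, v in MATERIAL_NAMES.items()}
        table = {
            name_to_code[name]: (float(v["mr"]), float(v["xray"]))
            for name, v in raw.items()
        }
        return cls(table)


def _ellipsoid_mask(coords, center, semi_axes, rot=None):
    d = coords - np.asarray(center)
    if rot is not None:
        d = d @ rot.T
    return np.sum((d / np.asarray(semi_axes)) ** 2, axis=-1) <= 1.0


def _capsule_mask(coords, p0, p1, radius):
    """Voxels within ``radius`` of the segment p0-p1 (a tube with round caps)."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    seg = p1 - p0
    L2 = float(seg @ seg)
    d = coords - p0
    t = np.clip((d @ seg) / max(L2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    return np.sum((coords - closest) ** 2, axis=-1) <= radius**2


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_phantom(
    shape: tuple[int, int, int],
    spacing_mm=(1.0, 1.0, 1.0),
    seed: int = 0,
    n_inner_structures: int = 5,
    shell_fraction: float = 0.42,
    shell_thickness_fraction: float = 0.10,
    axial_truncation: float = 0.0,
) -> MaterialPhantom:
    """Generate a seeded material phantom.

    An outer ellipsoidal bone shell (semi-axes ``shell_fraction`` of the grid
    half-extent, thickness ``shell_thickness_fraction`` of the semi-axes)
    encloses soft tissue; ``n_inner_structures`` inner bone ellipsoids or
    vessel capsules are drawn with the seeded generator from uniform ranges
    (centers within 60% of the inner region, ellipsoid semi-axes 4-12% and
    capsule radii 1.5-4% of the grid extent).  ``axial_truncation`` in [0, 0.5)
    blanks that fraction of slices at each axial end, emulating incompletely
    acquired head scans.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 16 for s in shape):
        raise ValueError("phantom shape components must be >= 16")
    if not (0.0 <= axial_truncation < 0.5):
        raise ValueError("axial_truncation must be in [0, 0.5)")
    ext = np.array(shape, float)
    semi_outer = shell_fraction * ext
    if np.any(semi_outer > ext / 2):
        raise ValueError("shell radii exceed the grid extent")

    rng = np.random.default_rng(seed)
    center = (ext - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1)

    labels = np.full(shape, AIR, dtype=np.uint8)
    outer = _ellipsoid_mask(coords, center, semi_outer)
    semi_inner = semi_outer * (1.0 - shell_thickness_fraction)
    inner = _ellipsoid_mask(coords, center, semi_inner)
    labels[outer] = BONE
    labels[inner] = SOFT

    max_ext = float(np.max(ext))
    for _ in range(n_inner_structures):
        kind = rng.choice(["bone_ellipsoid", "vessel_tube"])
        c = center + rng.uniform(-0.6, 0.6, size=3) * semi_inner
        if kind == "bone_ellipsoid":
            axes = rng.uniform(0.04, 0.12, size=3) * max_ext
            rot = _random_rotation(rng)
            mask = _ellipsoid_mask(coords, c, axes, rot)
            labels[mask & inner] = BONE
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            half_len = rng.uniform(0.15, 0.45) * max_ext / 2
            radius = rng.uniform(0.015, 0.04) * max_ext
            mask = _capsule_mask(coords, c - half_len * direction, c + half_len * direction, radius)
            labels[mask & inner] = VESSEL

    if axial_truncation > 0:
        n_cut = int(round(axial_truncation * shape[2]))
        if n_cut:
            labels[:, :, :n_cut] = AIR
            labels[:, :, -n_cut:] = AIR

    return MaterialPhantom(labels, spacing_mm, seed)


def render_pair(phantom: MaterialPhantom, mapping: ModalityMapping | None = None) -> tuple[Volume, Volume]:
    """Render a phantom into co-registered (mr_volume, xray_volume)."""
    if mapping is None:
        mapping = ModalityMapping()
    present = set(np.unique(phantom.labels).tolist())
    missing = present - set(mapping.table)
    if missing:
        raise ValueError(f"mapping missing materials: {sorted(missing)}")
    mr_lut = np.zeros(max(mapping.table) + 1)
    xr_lut = np.zeros(max(mapping.table) + 1)
    for code, (mr, mu) in mapping.table.items():
        mr_lut[code] = mr
        xr_lut[code] = mu
    mr_vol = Volume.centered(mr_lut[phantom.labels], phantom.spacing_mm)
    xr_vol = Volume.centered(xr_lut[phantom.labels], phantom.spacing_mm)
    return mr_vol, xr_vol


def make_dataset(
    out_dir,
    n_subjects: int,
    n_train_views: int,
    n_test_views: int,
    geometry: ConeBeamGeometry | None = None,
    seed: int = 0,
    phantom_shape=(64, 64, 64),
    phantom_spacing=(1.0, 1.0, 1.0),
    mapping: ModalityMapping | None = None,
    step_mm: float | None = None,
) -> Path:
    """Render and project a full paired dataset to disk.

    Layout: ``subject_XX/{train,test}/{mr,xray}/view_####.tif`` plus a
    ``geometry.json`` sidecar per subject recording geometry and view lists.
    Fully reproducible from ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if geometry is None:
        geometry = ConeBeamGeometry(detector_shape=(64, 64), detector_spacing_mm=(4.0, 4.0))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    train_views = make_trajectory(n_train_views, "training_sphere")
    test_views = make_trajectory(n_test_views, "test_transversal")
    root_rng = np.random.default_rng(seed)
    subject_seeds = root_rng.integers(0, 2**31 - 1, size=n_subjects)

    for s, sseed in enumerate(subject_seeds):
        sdir = out_dir / f"subject_{s:02d}"
        phantom = make_phantom(phantom_shape, spacing_mm=phantom_spacing, seed=int(sseed))
        mr_vol, xr_vol = render_pair(phantom, mapping)
        for split, views in (("train", train_views), ("test", test_views)):
            for mod in ("mr", "xray"):
                (sdir / split / mod).mkdir(parents=True, exist_ok=True)
            for i, view in enumerate(views):
                pair = project_pair(mr_vol, xr_vol, geometry, view, step_mm)
                proj_io.write_projection(sdir / split / "mr" / f"view_{i:04d}.tif", pair.mr)
                proj_io.write_projection(sdir / split / "xray" / f"view_{i:04d}.tif", pair.xray)
        sidecar = {
            "geometry": geometry.to_dict(),
            "train_views": [list(v) for v in train_views],
            "test_views": [list(v) for v in test_views],
            "phantom": {"shape": list(phantom_shape), "spacing": list(phantom_spacing),
                        "seed": int(sseed)},
        }
        with open(sdir / "geometry.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
    return out_dir
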