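"""File I/O: volumes (NIfTI / MetaImage) and projection images (float TIFF).

Volumes are read with their header spacing; the array axes are assumed
world-aligned (rigid rotations in headers are not applied — input data are
expected co-registered and axis-aligned).  Projections are written as 32-bit
float TIFF, one file per view, with dataset-level geometry recorded in a JSON
sidecar by the callers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .geometry import Volume
from .projector import ProjectionImage

__all__ = ["read_volume", "write_projection", "read_projection"]


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing comes from the header; the volume is centered at the isocenter.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float64)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    elif name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
        values = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=np.float64)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return Volume.centered(values, spacing)


def write_projection(path, image: ProjectionImage) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_projection(path, view=(0.0, 0.0), modality_tag: str = "xray") -> ProjectionImage:
    pixels = tifffile.imread(str(path)).astype(np.float64)
    return ProjectionImage(pixels, tuple(view), modality_tag)
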