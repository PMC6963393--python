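"""Volumes, masks and ROI point sets with explicit voxel geometry.

Conventions
-----------
* Arrays are indexed ``(i, j, k)`` = (x, y, slice); axis 2 is the slice axis
  (the 1 mm slice-thickness direction of the emulated MPRAGE protocol).
* All coordinates are **0-based voxel indices**.  Clinical viewers number
  slices from 1 on screen; everything in this package does not.
* Spacing is millimetres per voxel along each axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "ROIPointSet",
    "read_volume",
    "write_volume",
    "read_roi",
    "write_roi",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for files that do not satisfy the 3-D-volume contract."""


@dataclass
class Volume3D:
    """A 3-D scalar MR-like volume.

    Parameters
    ----------
    data : ndarray
        3-D array of intensities (arbitrary units).
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm; all components > 0.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.  Informational only.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.31, 0.31, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class ROIPointSet:
    """A labelled set of voxel coordinates, e.g. the three SCM sample points.

    Points are 0-based ``(i, j, k)`` voxel indices.
    """

    points: list[tuple[int, int, int]]
    label: str = "SCM"

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("ROI point set must contain at least one point")
        clean = []
        for p in self.points:
            if len(p) != 3:
                raise ValueError(f"point {p!r} is not a coordinate triple")
            for c in p:
                if float(c) != int(c):
                    raise ValueError(f"non-integer coordinate in point {p!r}")
            if any(int(c) < 0 for c in p):
                raise ValueError(f"negative coordinate in point {p!r}")
            clean.append(tuple(int(c) for c in p))
        self.points = clean

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        for p in self.points:
            if any(c >= s for c, s in zip(p, shape)):
                raise ValueError(f"point {p} outside grid of shape {shape}")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume3D, path, *, as_mask: bool = False) -> None:
    """Write a volume (or binary mask) to NIfTI-1 with spacing in the header.

    Masks are stored as 8-bit 0/1; volumes as float32.
    """
    if as_mask:
        data = (np.asarray(volume.data) != 0).astype(np.uint8)
    else:
        data = np.asarray(volume.data, dtype=np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    """Read a NIfTI volume, rejecting anything that is not a proper 3-D grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: missing or zero voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume3D(data=np.asarray(data, dtype=np.float64), spacing=zooms, origin=origin)


def write_roi(roi: ROIPointSet, path) -> None:
    with open(path, "w") as fh:
        json.dump({"label": roi.label, "points": [list(p) for p in roi.points]}, fh, indent=2)


def read_roi(path, grid_shape: tuple[int, int, int] | None = None) -> ROIPointSet:
    """Read a JSON ROI point set; optionally validate against a grid shape."""
    with open(path) as fh:
        payload = json.load(fh)
    roi = ROIPointSet(points=[tuple(p) for p in payload["points"]],
                      label=payload.get("label", "ROI"))
    if grid_shape is not None:
        roi.validate_bounds(tuple(grid_shape))
    return roi
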