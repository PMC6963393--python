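"""Semi-automatic IPH segmentation: muscle-referenced intensity thresholds.

The protocol emulated here defines IPH as plaque voxels whose signal exceeds
a fixed percentage (150%, 175% or 200%) of the mean intensity of three sample
points placed in the sternocleidomastoid muscle (SCM), retained only where
the hyperintensity persists for at least two consecutive slices.  Three
metrics are derived from the final mask: total IPH volume, maximal axial
(single-slice) IPH volume, and IPH length along the slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Volume3D, ROIPointSet

__all__ = [
    "ReferenceIntensity", "ThresholdCriterion", "IPHMetrics", "IPHSegmentation",
    "sample_muscle_reference", "qualify_plaque", "threshold_iph",
    "enforce_consecutive_slices", "compute_metrics", "segment_iph",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ReferenceIntensity:
    """Mean SCM signal from a small number of sampled points (μ_SCM)."""
    mean: float
    point_values: tuple[float, ...]
    n_points: int


@dataclass
class ThresholdCriterion:
    """A voxel passes iff its value > ratio × μ_SCM (strict by default)."""
    ratio: float
    strict: bool = True

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("threshold ratio must be > 0")

    @property
    def label(self) -> str:
        return f"{round(self.ratio * 100):d}%"


@dataclass
class IPHMetrics:
    total_volume: float       # mm³
    max_axial_volume: float   # mm³, largest single-slice contribution
    length: float             # mm, occupied slice span × slice thickness


@dataclass
class IPHSegmentation:
    """A binary IPH mask with its derived metrics and provenance."""
    mask: np.ndarray
    metrics: IPHMetrics
    criterion: ThresholdCriterion | str
    reference: ReferenceIntensity | None = None
    extra: dict = field(default_factory=dict)


def sample_muscle_reference(volume: Volume3D, roi: ROIPointSet,
                            required_points: int | None = 3) -> ReferenceIntensity:
    """Arithmetic mean of the voxel values at the ROI points.

    The default policy requires exactly 3 points, matching the reading
    protocol; pass ``required_points=None`` to accept any number >= 1.
    """
    if required_points is not None and len(roi) != required_points:
        raise ValueError(
            f"reference policy requires exactly {required_points} points, got {len(roi)}")
    roi.validate_bounds(volume.shape)
    values = tuple(float(volume.data[p]) for p in roi.points)
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError(f"muscle reference mean must be > 0, got {mean}")
    return ReferenceIntensity(mean=mean, point_values=values, n_points=len(values))


def qualify_plaque(wall_thickness_by_slice) -> bool:
    """Plaque qualification: wall thickness > 2 mm on >= 2 consecutive slices."""
    thick = [float(t) for t in wall_thickness_by_slice]
    if len(thick) == 0:
        raise ValueError("wall thickness list must be non-empty")
    if any(t < 0 for t in thick):
        raise ValueError("wall thickness cannot be negative")
    return any(a > 2.0 and b > 2.0 for a, b in zip(thick, thick[1:]))


def threshold_iph(volume: Volume3D, plaque_mask: np.ndarray,
                  ref: ReferenceIntensity, criterion: ThresholdCriterion) -> np.ndarray:
    """Candidate IPH mask: plaque voxels exceeding ratio × μ_SCM.

    No connectivity filtering is applied here; the consecutive-slice rule is
    a separate stage.
    """
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    if plaque_mask.shape != volume.shape:
        raise ValueError(
            f"plaque mask shape {plaque_mask.shape} != volume shape {volume.shape}")
    if ref.mean <= 0:
        raise ValueError("reference mean must be > 0")
    cutoff = criterion.ratio * ref.mean
    if criterion.strict:
        passed = volume.data > cutoff
    else:
        passed = volume.data >= cutoff
    return plaque_mask & passed


def _has_consecutive_run(slices: np.ndarray, min_slices: int) -> bool:
    """True iff the sorted unique slice indices contain a run of length
    >= min_slices of consecutive integers."""
    slices = np.unique(slices)
    if min_slices <= 1:
        return slices.size >= 1
    run = 1
    for prev, cur in zip(slices, slices[1:]):
        run = run + 1 if cur == prev + 1 else 1
        if run >= min_slices:
            return True
    return False


def enforce_consecutive_slices(mask: np.ndarray, min_slices: int = 2,
                               connectivity: int = 26,
                               scope: str = "component") -> np.ndarray:
    """Remove hyperintense regions not persisting over consecutive slices.

    Connected components (default 26-connectivity) whose slice-index support
    lacks ``min_slices`` consecutive indices are removed entirely.  With
    ``scope='mask'`` the rule is instead applied to the mask as a whole: if
    the union support lacks the run, the whole mask is cleared.
    """
    if min_slices < 1:
        raise ValueError("min_slices must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        return mask.copy()
    if scope == "mask":
        ks = np.unique(np.nonzero(mask)[2])
        return mask.copy() if _has_consecutive_run(ks, min_slices) else np.zeros_like(mask)
    if scope != "component":
        raise ValueError(f"unknown scope {scope!r}")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    out = np.zeros_like(mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        ks = np.unique(np.nonzero(comp)[2])
        if _has_consecutive_run(ks, min_slices):
            out |= comp
    return out


def compute_metrics(mask: np.ndarray, spacing) -> IPHMetrics:
    """Total volume, maximal axial volume and slice-axis length of a mask.

    * total_volume = voxel count × dx·dy·dz
    * max_axial_volume = max over slices of per-slice count × voxel volume
    * length = (max occupied slice − min occupied slice + 1) × dz
    """
    mask = np.asarray(mask, dtype=bool)
    dx, dy, dz = (float(s) for s in spacing)
    voxvol = dx * dy * dz
    if not mask.any():
        return IPHMetrics(0.0, 0.0, 0.0)
    per_slice = mask.sum(axis=(0, 1))
    occupied = np.nonzero(per_slice)[0]
    return IPHMetrics(
        total_volume=float(mask.sum()) * voxvol,
        max_axial_volume=float(per_slice.max()) * voxvol,
        length=float(occupied.max() - occupied.min() + 1) * dz,
    )


def segment_iph(volume: Volume3D, plaque_mask: np.ndarray, roi: ROIPointSet,
                criterion: ThresholdCriterion, *, min_slices: int = 2,
                connectivity: int = 26, scope: str = "component",
                required_points: int | None = 3) -> IPHSegmentation:
    """Full semi-automatic pipeline.

    Composition: muscle reference → intensity threshold → consecutive-slice
    rule → metrics.  All settings are recorded in the returned segmentation.
    """
    ref = sample_muscle_reference(volume, roi, required_points=required_points)
    candidate = threshold_iph(volume, plaque_mask, ref, criterion)
    mask = enforce_consecutive_slices(candidate, min_slices=min_slices,
                                      connectivity=connectivity, scope=scope)
    metrics = compute_metrics(mask, volume.spacing)
    return IPHSegmentation(
        mask=mask, metrics=metrics, criterion=criterion, reference=ref,
        extra={"min_slices": min_slices, "connectivity": connectivity, "scope": scope},
    )
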