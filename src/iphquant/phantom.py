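"""Synthetic carotid-plaque phantoms with known IPH ground truth.

Each subject is a small 3-D volume emulating the intensity structure an
MPRAGE-based IPH analysis relies on: a dark lumen (black blood), a vessel
wall carrying an eccentric plaque, an ellipsoidal intraplaque hemorrhage
whose intensity is a configurable multiple of the muscle mean, a
sternocleidomastoid-muscle block used as the intensity reference, and
magnitude-image (Rician) noise.  Geometry uses exact analytic primitives
(cylinder, angular sector, ellipsoid) evaluated at voxel centres so that the
true IPH volume is an exact voxel count times the voxel volume; anatomical
realism is a non-goal.

Axis 2 (k) is the slice axis; physical coordinates are voxel index x spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .image_io import Volume3D, ROIPointSet

__all__ = [
    "VesselSpec", "PlaqueSpec", "IPHSpec", "MuscleSpec", "NoiseSpec",
    "PhantomConfig", "SubjectTruth", "CohortSpec",
    "add_noise", "generate_subject", "generate_cohort", "default_scm_roi",
    "PhantomGeometryError",
]


class PhantomGeometryError(ValueError):
    """A phantom configuration violates a geometric constraint."""


@dataclass
class VesselSpec:
    """Straight vessel along the slice axis."""
    center_mm: tuple[float, float] = (6.2, 9.92)   # axis position in the xy plane
    lumen_radius_mm: float = 2.5
    wall_thickness_mm: float = 1.0


@dataclass
class PlaqueSpec:
    """Eccentric wall thickening over an angular sector and a slice span."""
    angle_center_deg: float = 0.0
    angle_width_deg: float = 140.0
    thickness_mm: float = 2.5            # radial thickening beyond the normal wall
    slice_range: tuple[int, int] = (2, 13)  # inclusive slice indices


@dataclass
class IPHSpec:
    """Ellipsoidal hemorrhage embedded in the plaque."""
    semi_axes_mm: tuple[float, float, float] = (1.0, 2.2, 3.0)
    center_mm: tuple[float, float, float] = (10.95, 9.92, 7.5)
    intensity_ratio: float = 2.0         # IPH intensity / muscle mean


@dataclass
class MuscleSpec:
    """Rectangular SCM block (voxel index ranges, half-open)."""
    index_range: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (44, 59), (8, 25), (0, 16))
    mean_intensity: float = 100.0
    sd: float = 5.0                      # intra-ROI variability


@dataclass
class NoiseSpec:
    model: str = "rician"
    sigma: float = 5.0


@dataclass
class PhantomConfig:
    """Full description of one synthetic subject."""
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (0.31, 0.31, 1.0)
    vessel: VesselSpec = field(default_factory=VesselSpec)
    plaque: PlaqueSpec = field(default_factory=PlaqueSpec)
    iph: IPHSpec = field(default_factory=IPHSpec)
    muscle: MuscleSpec = field(default_factory=MuscleSpec)
    background_intensity: float = 20.0
    lumen_intensity: float = 10.0
    wall_intensity: float | None = None  # defaults to the muscle mean (isointense wall)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) < 1 for s in self.grid_shape):
            raise PhantomGeometryError("grid_shape components must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise PhantomGeometryError("spacing components must be > 0")
        if self.vessel.lumen_radius_mm <= 0 or self.vessel.wall_thickness_mm <= 0:
            raise PhantomGeometryError("vessel radii/thicknesses must be > 0")
        if self.plaque.thickness_mm <= 0:
            raise PhantomGeometryError("plaque thickness must be > 0")
        if any(a <= 0 for a in self.iph.semi_axes_mm):
            raise PhantomGeometryError("IPH semi-axes must be > 0")
        if self.iph.intensity_ratio <= 0:
            raise PhantomGeometryError("intensity_ratio must be > 0")
        if self.muscle.mean_intensity <= 0:
            raise PhantomGeometryError("muscle mean intensity must be > 0")
        if self.noise.sigma < 0:
            raise PhantomGeometryError("noise sigma must be >= 0")


@dataclass
class SubjectTruth:
    """Ground-truth masks and parameters for one synthetic subject."""
    plaque_mask: np.ndarray
    iph_mask: np.ndarray
    muscle_mask: np.ndarray
    true_iph_volume: float               # mm³, exactly voxel count x voxel volume
    intensity_ratio: float
    seed: int

    def params_dict(self) -> dict:
        return {
            "true_iph_volume_mm3": self.true_iph_volume,
            "intensity_ratio": self.intensity_ratio,
            "seed": self.seed,
            "iph_voxels": int(self.iph_mask.sum()),
        }


@dataclass
class CohortSpec:
    """A cohort of subjects drawn from per-subject parameter distributions.

    ``ratio_range`` and the semi-axis ranges are uniform distributions; a
    degenerate range (lo == hi) fixes the parameter.  The default cohort size
    matches the emulated study population of 40 subjects.
    """
    n_subjects: int = 40
    ratio_range: tuple[float, float] = (1.3, 3.0)
    semi_axis_a_range: tuple[float, float] = (0.8, 1.2)   # radial, mm
    semi_axis_b_range: tuple[float, float] = (1.5, 3.0)   # tangential, mm
    semi_axis_c_range: tuple[float, float] = (2.0, 5.0)   # axial, mm
    template: PhantomConfig = field(default_factory=PhantomConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (agreement statistics undefined)")
        lo, hi = self.ratio_range
        if lo <= 0 or hi < lo:
            raise ValueError("ratio distribution support must be > 0 and ordered")


def add_noise(volume: Volume3D, model: str, sigma: float, seed: int) -> Volume3D:
    """Corrupt a volume with MR-appropriate noise.

    ``rician`` applies magnitude-of-complex-Gaussian corruption
    (sqrt((I + n1)² + n2²) with n1, n2 ~ N(0, sigma²)), the statistics of MR
    magnitude images; ``gaussian`` adds zero-mean noise.  sigma = 0 returns
    the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    data = np.asarray(volume.data, dtype=np.float64)
    if model == "rician":
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        noisy = np.hypot(data + n1, n2)
    elif model == "gaussian":
        noisy = data + rng.normal(0.0, sigma, size=data.shape)
    else:
        raise ValueError(f"unknown noise model {model!r} (expected 'rician' or 'gaussian')")
    return Volume3D(data=noisy, spacing=volume.spacing, origin=volume.origin)


def _coordinate_grids(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.spacing
    x = np.arange(nx)[:, None, None] * dx
    y = np.arange(ny)[None, :, None] * dy
    z = np.arange(nz)[None, None, :] * dz
    return x, y, z


def _build_masks(config: PhantomConfig):
    """Evaluate the analytic geometry at voxel centres."""
    x, y, z = _coordinate_grids(config)
    cx, cy = config.vessel.center_mm
    r = np.hypot(x - cx, y - cy)
    r = np.broadcast_to(r, config.grid_shape)

    lumen = r < config.vessel.lumen_radius_mm
    wall_outer = config.vessel.lumen_radius_mm + config.vessel.wall_thickness_mm
    wall = (r >= config.vessel.lumen_radius_mm) & (r < wall_outer)

    theta = np.degrees(np.arctan2(np.broadcast_to(y - cy, config.grid_shape),
                                  np.broadcast_to(x - cx, config.grid_shape)))
    dtheta = (theta - config.plaque.angle_center_deg + 180.0) % 360.0 - 180.0
    in_sector = np.abs(dtheta) <= config.plaque.angle_width_deg / 2.0
    k = np.broadcast_to(np.arange(config.grid_shape[2])[None, None, :], config.grid_shape)
    k0, k1 = config.plaque.slice_range
    in_span = (k >= k0) & (k <= k1)
    plaque_outer = wall_outer + config.plaque.thickness_mm
    plaque = (in_sector & in_span
              & (r >= config.vessel.lumen_radius_mm) & (r < plaque_outer))

    a, b, c = config.iph.semi_axes_mm
    ix, iy, iz = config.iph.center_mm
    iph = (((x - ix) / a) ** 2 + ((y - iy) / b) ** 2 + ((z - iz) / c) ** 2) < 1.0
    iph = np.broadcast_to(iph, config.grid_shape) & np.ones(config.grid_shape, bool)

    muscle = np.zeros(config.grid_shape, bool)
    (i0, i1), (j0, j1), (kk0, kk1) = config.muscle.index_range
    muscle[i0:i1, j0:j1, kk0:kk1] = True

    if np.any(iph & ~plaque):
        raise PhantomGeometryError(
            "IPH ellipsoid is not contained in the plaque region "
            "(constraint: iph_mask subset of plaque_mask)")
    if np.any(muscle & (r < plaque_outer)):
        raise PhantomGeometryError(
            "muscle block overlaps the vessel/plaque region "
            "(constraint: muscle disjoint from vessel)")
    return lumen, wall, plaque, iph, muscle


def generate_subject(config: PhantomConfig) -> tuple[Volume3D, SubjectTruth]:
    """Render one subject: noiseless composition followed by noise.

    Noiseless IPH voxels equal exactly ``intensity_ratio × muscle mean``;
    the output is deterministic for a fixed ``config.seed``.
    """
    lumen, wall, plaque, iph, muscle = _build_masks(config)
    wall_val = (config.wall_intensity if config.wall_intensity is not None
                else config.muscle.mean_intensity)

    data = np.full(config.grid_shape, float(config.background_intensity))
    data[wall | plaque] = wall_val
    data[lumen] = config.lumen_intensity
    rng = np.random.default_rng(config.seed)
    n_mus = int(muscle.sum())
    data[muscle] = rng.normal(config.muscle.mean_intensity, config.muscle.sd, size=n_mus)
    data[iph] = config.iph.intensity_ratio * config.muscle.mean_intensity

    clean = Volume3D(data=data, spacing=config.spacing)
    noisy = add_noise(clean, config.noise.model, config.noise.sigma,
                      seed=config.seed + 1)

    voxvol = clean.voxel_volume
    truth = SubjectTruth(
        plaque_mask=plaque,
        iph_mask=iph,
        muscle_mask=muscle,
        true_iph_volume=float(iph.sum()) * voxvol,
        intensity_ratio=config.iph.intensity_ratio,
        seed=config.seed,
    )
    return noisy, truth


def default_scm_roi(config: PhantomConfig, n_points: int = 3) -> ROIPointSet:
    """Deterministic SCM sample points inside the muscle block.

    Mimics the reader placing three cursor points in the muscle belly: points
    are spread around the block centre, never on its border.
    """
    (i0, i1), (j0, j1), (k0, k1) = config.muscle.index_range
    ci, cj, ck = (i0 + i1) // 2, (j0 + j1) // 2, (k0 + k1) // 2
    offsets = [(0, 0, 0), (-3, -2, -1), (3, 2, 1), (-2, 3, 1), (2, -3, -1)]
    pts = []
    for di, dj, dk in offsets[:n_points]:
        pts.append((int(np.clip(ci + di, i0, i1 - 1)),
                    int(np.clip(cj + dj, j0, j1 - 1)),
                    int(np.clip(ck + dk, k0, k1 - 1))))
    return ROIPointSet(points=pts, label="SCM")


def generate_cohort(spec: CohortSpec) -> list[tuple[Volume3D, SubjectTruth]]:
    """Generate ``n_subjects`` subjects with per-subject parameters and seeds
    derived reproducibly from the master seed."""
    master = np.random.default_rng(spec.master_seed)
    subjects = []
    for idx in range(spec.n_subjects):
        ratio = float(master.uniform(*spec.ratio_range))
        a = float(master.uniform(*spec.semi_axis_a_range))
        b = float(master.uniform(*spec.semi_axis_b_range))
        c = float(master.uniform(*spec.semi_axis_c_range))
        subj_seed = int(master.integers(0, 2**31 - 1))
        t = spec.template
        config = PhantomConfig(
            grid_shape=t.grid_shape,
            spacing=t.spacing,
            vessel=t.vessel,
            plaque=t.plaque,
            iph=IPHSpec(semi_axes_mm=(a, b, c), center_mm=t.iph.center_mm,
                        intensity_ratio=ratio),
            muscle=t.muscle,
            background_intensity=t.background_intensity,
            lumen_intensity=t.lumen_intensity,
            wall_intensity=t.wall_intensity,
            noise=t.noise,
            seed=subj_seed,
        )
        subjects.append(generate_subject(config))
    return subjects
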