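"""Digital phantoms and paired liver studies with known ground truth.

Two families of synthetic inputs make every downstream stage testable
without clinical data:

* a digital Jaszczak-style quality-control phantom — a ~6 L activity-filled
  cylinder containing eight fillable spheres (diameters 2–34 mm) at a 13:1
  sphere-to-background activity-concentration ratio (0.52 vs 0.04 MBq/ml),
  the configuration used to calibrate the contrast-recovery stopping rule;
* paired planning/post-therapy liver studies — an ellipsoidal liver with
  one or more high-uptake tumor blobs (known true tumor-to-liver ratio,
  optional necrotic core, optional rigid misalignment between the pair).

Rasterisation handles partial volume at region boundaries by supersampled
occupancy fractions (default 4³ sub-voxels per boundary voxel), so stated
activity *concentrations* are the primary ground truth; per-region activity
follows as concentration × volume.

The forward acquisition model is deliberately minimal: multiply by a
calibration factor (cps/MBq), blur with the isotropic Gaussian
collimator–detector PSF, and optionally draw Poisson counts at a given
acquisition time.  There is no projector, attenuation, scatter or septal
penetration — the degradations a real bremsstrahlung acquisition adds on
top are out of scope here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

import yaml

from .imgcore import StudySet, VoiMask, VoxelGrid, require_units
from .recover import PsfModel, blur

__all__ = [
    "SphereSpec",
    "PhantomSpec",
    "AcquisitionModel",
    "TumorSpec",
    "LiverStudySpec",
    "rasterize_phantom",
    "simulate_acquisition",
    "rasterize_liver_study",
    "make_paired_study",
    "make_cohort",
]

#: Jaszczak insert inner diameters, mm (largest first).
JASZCZAK_DIAMETERS = (34.0, 31.0, 25.0, 16.0, 12.0, 10.0, 8.0, 2.0)
SPHERE_CONCENTRATION = 0.52  # MBq/ml
BACKGROUND_CONCENTRATION = 0.04  # MBq/ml  (13:1 hot-sphere ratio)


@dataclass(frozen=True)
class SphereSpec:
    center: tuple[float, float, float]  # world mm
    diameter: float  # mm
    concentration: float  # MBq/ml

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class PhantomSpec:
    """Cylindrical phantom with hot-sphere inserts on a centred grid."""

    cylinder_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cylinder_radius: float = 102.0  # mm -> ~6.1 L with the default height
    cylinder_height: float = 186.0  # mm
    background_concentration: float = BACKGROUND_CONCENTRATION
    spheres: list[SphereSpec] = field(default_factory=list)
    voxel_size: float = 4.664  # mm, isotropic
    shape: tuple[int, int, int] = (96, 96, 64)
    supersampling: int = 4

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        for s in self.spheres:
            r = s.diameter / 2.0
            dx = s.center[0] - self.cylinder_center[0]
            dy = s.center[1] - self.cylinder_center[1]
            dz = s.center[2] - self.cylinder_center[2]
            if np.hypot(dx, dy) + r > self.cylinder_radius or abs(dz) + r > self.cylinder_height / 2:
                raise ValueError(f"sphere at {s.center} (d={s.diameter}) lies outside the cylinder")

    @classmethod
    def jaszczak(cls, ring_radius: float = 60.0, **kwargs) -> "PhantomSpec":
        """Default eight-sphere phantom: inserts on a ring in the central slice."""
        angles = np.linspace(0.0, 2 * np.pi, len(JASZCZAK_DIAMETERS), endpoint=False)
        spheres = [
            SphereSpec(
                center=(ring_radius * np.cos(a), ring_radius * np.sin(a), 0.0),
                diameter=d,
                concentration=SPHERE_CONCENTRATION,
            )
            for d, a in zip(JASZCZAK_DIAMETERS, angles)
        ]
        return cls(spheres=spheres, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        spheres = [SphereSpec(tuple(s["center"]), s["diameter"], s["concentration"])
                   for s in cfg.pop("spheres", [])]
        for key in ("cylinder_center", "shape"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        if spheres:
            return cls(spheres=spheres, **cfg)
        return cls.jaszczak(**cfg)

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(-(n - 1) / 2.0 * self.voxel_size for n in self.shape)  # type: ignore

    @property
    def concentration_ratio(self) -> float:
        """Sphere:background activity-concentration ratio."""
        if not self.spheres or self.background_concentration == 0:
            raise ValueError("ratio undefined")
        return self.spheres[0].concentration / self.background_concentration


@dataclass(frozen=True)
class AcquisitionModel:
    """Forward model: CF scaling, Gaussian PSF blur, optional Poisson noise."""

    cf: float = 9049.0  # cps/MBq — phantom-regime count level
    psf_fwhm: float = 12.0  # mm
    noise: str = "poisson"  # "poisson" | "none"
    acquisition_seconds: float = 35.0  # scales counts for Poisson draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("cf must be > 0")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.acquisition_seconds <= 0:
            raise ValueError("acquisition_seconds must be > 0")
        if self.noise not in {"poisson", "none"}:
            raise ValueError(f"noise must be 'poisson' or 'none', got {self.noise!r}")


# ---------------------------------------------------------------------------
# Occupancy rasterisation (supersampled partial volume)
# ---------------------------------------------------------------------------

def _world_centers(shape, spacing, origin):
    idx = np.indices(shape, dtype=np.float64)
    return [origin[ax] + idx[ax] * spacing[ax] for ax in range(3)]


def _subvoxel_offsets(spacing: float, s: int) -> np.ndarray:
    """(s³, 3) world-mm offsets of sub-voxel centres from the voxel centre."""
    t = (np.arange(s) + 0.5) / s - 0.5
    gx, gy, gz = np.meshgrid(t, t, t, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) * spacing


def _band_fractions(band_idx, spacing, origin, inside_fn, s: int) -> np.ndarray:
    offs = _subvoxel_offsets(spacing, s)  # isotropic voxels
    centers = band_idx * spacing + np.asarray(origin)  # (N, 3)
    pts = centers[:, None, :] + offs[None, :, :]  # (N, s³, 3)
    return inside_fn(pts).mean(axis=1)


def _sphere_occupancy(shape, spacing, origin, center, radius, s: int) -> np.ndarray:
    x, y, z = _world_centers(shape, (spacing,) * 3, origin)
    c = np.asarray(center)
    dist = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
    half_diag = spacing * np.sqrt(3) / 2.0
    occ = np.zeros(shape)
    occ[dist <= radius - half_diag] = 1.0
    band = np.abs(dist - radius) < half_diag
    if band.any():
        idx = np.argwhere(band)
        frac = _band_fractions(
            idx, spacing, origin,
            lambda p: ((p - c) ** 2).sum(axis=-1) <= radius**2, s,
        )
        occ[band] = frac
    return occ


def _cylinder_occupancy(shape, spacing, origin, center, radius, height, s: int) -> np.ndarray:
    x, y, z = _world_centers(shape, (spacing,) * 3, origin)
    c = np.asarray(center)
    radial = np.hypot(x - c[0], y - c[1])
    axial = np.abs(z - c[2])
    half_diag = spacing * np.sqrt(3) / 2.0
    occ = np.zeros(shape)
    occ[(radial <= radius - half_diag) & (axial <= height / 2 - half_diag)] = 1.0
    inside_loose = (radial < radius + half_diag) & (axial < height / 2 + half_diag)
    band = inside_loose & (occ == 0.0)
    if band.any():
        idx = np.argwhere(band)

        def inside(p):
            r = np.hypot(p[..., 0] - c[0], p[..., 1] - c[1])
            return (r <= radius) & (np.abs(p[..., 2] - c[2]) <= height / 2)

        occ[band] = _band_fractions(idx, spacing, origin, inside, s)
    return occ


def _ellipsoid_occupancy(shape, spacing, origin, center, axes, s: int) -> np.ndarray:
    x, y, z = _world_centers(shape, (spacing,) * 3, origin)
    c, a = np.asarray(center), np.asarray(axes)
    rho = np.sqrt(
        ((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2 + ((z - c[2]) / a[2]) ** 2
    )
    # rho is 1/min(axes)-Lipschitz, so this band provably brackets the surface
    tol = spacing * np.sqrt(3) / 2.0 / a.min()
    occ = np.zeros(shape)
    occ[rho <= 1.0 - tol] = 1.0
    band = np.abs(rho - 1.0) < tol
    if band.any():
        idx = np.argwhere(band)
        occ[band] = _band_fractions(
            idx, spacing, origin,
            lambda p: (((p - c) / a) ** 2).sum(axis=-1) <= 1.0, s,
        )
    return occ


# ---------------------------------------------------------------------------
# Phantom rasterisation and acquisition
# ---------------------------------------------------------------------------

def rasterize_phantom(spec: PhantomSpec) -> dict:
    """Rasterise a phantom spec into an activity grid plus truth masks.

    Per-voxel activity is concentration × voxel volume, with boundary voxels
    fractionally weighted.  Truth masks: one per sphere (``sphere_<d>mm``;
    a sphere too small to reach 50% occupancy anywhere is represented by the
    voxel containing its centre), ``background`` (cylinder voxels free of any
    sphere overlap) and ``phantom`` (whole cylinder).
    """
    spacing, origin, s = spec.voxel_size, spec.origin, spec.supersampling
    vox_ml = spacing**3 / 1000.0
    cyl = _cylinder_occupancy(
        spec.shape, spacing, origin, spec.cylinder_center,
        spec.cylinder_radius, spec.cylinder_height, s,
    )
    sphere_occ = {}
    for sp in spec.spheres:
        key = f"sphere_{sp.diameter:g}mm"
        sphere_occ[key] = (sp, _sphere_occupancy(
            spec.shape, spacing, origin, sp.center, sp.diameter / 2.0, s))
    total_sph = np.zeros(spec.shape)
    for _, occ in sphere_occ.values():
        total_sph += occ
    activity = spec.background_concentration * np.clip(cyl - total_sph, 0.0, None)
    for sp, occ in sphere_occ.values():
        activity += sp.concentration * occ
    activity *= vox_ml

    truth_masks: dict[str, VoiMask] = {}
    truth_activities: dict[str, float] = {}
    for key, (sp, occ) in sphere_occ.items():
        m = occ >= 0.5
        if not m.any():
            m = np.zeros(spec.shape, bool)
            if occ.max() > 0:
                m[np.unravel_index(np.argmax(occ), spec.shape)] = True
            else:  # sub-voxel sphere: fall back to the voxel containing its centre
                idx = tuple(
                    int(np.clip(round((sp.center[ax] - origin[ax]) / spacing), 0,
                                spec.shape[ax] - 1))
                    for ax in range(3)
                )
                m[idx] = True
        truth_masks[key] = VoiMask(m, "sphere", key)
        truth_activities[key] = float(sp.concentration * occ.sum() * vox_ml)
    truth_masks["background"] = VoiMask((cyl >= 0.5) & (total_sph == 0), "background")
    truth_masks["phantom"] = VoiMask(cyl >= 0.5, "body", "phantom_boundary")
    truth_activities["background"] = float(
        spec.background_concentration * np.clip(cyl - total_sph, 0, None).sum() * vox_ml
    )
    return {
        "activity": VoxelGrid(activity, (spacing,) * 3, origin, "MBq"),
        "truth_masks": truth_masks,
        "truth_activities": truth_activities,
        "total_activity_MBq": float(activity.sum()),
    }


def simulate_acquisition(activity: VoxelGrid, model: AcquisitionModel) -> VoxelGrid:
    """Forward-model an activity map into a reconstructed count-rate image.

    Expected counts are Gaussian-blurred activity × CF; Poisson mode draws
    integer counts at ``acquisition_seconds`` scaling then divides back to
    cps.  Identical seed → identical output.
    """
    require_units(activity, "MBq")
    expected_cps = blur(activity.data * model.cf, PsfModel(model.psf_fwhm), activity.spacing)
    if model.noise == "poisson":
        rng = np.random.default_rng(model.seed)
        t = model.acquisition_seconds
        counts = rng.poisson(np.clip(expected_cps, 0, None) * t).astype(np.float64)
        expected_cps = counts / t
    return activity.with_data(expected_cps, units="cps")


# ---------------------------------------------------------------------------
# Liver studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TumorSpec:
    center: tuple[float, float, float]  # world mm
    axes: tuple[float, float, float]  # semi-axes, mm
    uptake_multiplier: float = 5.0  # true TLR
    necrotic_fraction: float = 0.0  # volume fraction with zero uptake

    def __post_init__(self) -> None:
        if self.uptake_multiplier <= 0:
            raise ValueError("uptake_multiplier must be > 0")
        if not 0.0 <= self.necrotic_fraction < 1.0:
            raise ValueError("necrotic_fraction must be in [0, 1)")


@dataclass
class LiverStudySpec:
    """Ellipsoidal liver with high-uptake tumor blobs on a centred grid."""

    liver_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liver_axes: tuple[float, float, float] = (90.0, 60.0, 50.0)
    tumors: list[TumorSpec] = field(
        default_factory=lambda: [TumorSpec((35.0, 15.0, 5.0), (32.0, 26.0, 24.0))]
    )
    misalignment: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, applied to study_b
    voxel_size: float = 4.664
    shape: tuple[int, int, int] = (64, 64, 48)
    supersampling: int = 4

    def __post_init__(self) -> None:
        c0, a0 = np.asarray(self.liver_center), np.asarray(self.liver_axes)
        u = _unit_directions()
        for t in self.tumors:
            surf = np.asarray(t.center) + u * np.asarray(t.axes)
            rho = np.sqrt((((surf - c0) / a0) ** 2).sum(axis=1))
            if np.any(rho > 1.0):
                raise ValueError(f"tumor at {t.center} extends outside the liver")

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(-(n - 1) / 2.0 * self.voxel_size for n in self.shape)  # type: ignore


def _unit_directions(n: int = 128) -> np.ndarray:
    """Deterministic quasi-uniform directions on the sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def rasterize_liver_study(spec: LiverStudySpec, administered_MBq: float) -> dict:
    """Activity grid with total activity exactly ``administered_MBq``.

    Healthy-liver concentration c is solved from the administered activity;
    each tumor carries c × uptake_multiplier (zero in a necrotic core).
    """
    spacing, origin, s = spec.voxel_size, spec.origin, spec.supersampling
    vox_ml = spacing**3 / 1000.0
    liver = _ellipsoid_occupancy(spec.shape, spacing, origin, spec.liver_center, spec.liver_axes, s)
    weights = liver.copy()
    tumor_occ_total = np.zeros(spec.shape)
    tumor_masks: list[np.ndarray] = []
    for t in spec.tumors:
        occ = _ellipsoid_occupancy(spec.shape, spacing, origin, t.center, t.axes, s)
        active = occ
        if t.necrotic_fraction > 0:
            core_axes = tuple(a * t.necrotic_fraction ** (1 / 3) for a in t.axes)
            core = _ellipsoid_occupancy(spec.shape, spacing, origin, t.center, core_axes, s)
            active = np.clip(occ - core, 0.0, None)
        weights += t.uptake_multiplier * active - occ  # replace healthy by tumor uptake
        tumor_occ_total += occ
        tumor_masks.append(occ >= 0.5)
    c_healthy = administered_MBq / (weights.sum() * vox_ml)
    activity = c_healthy * weights * vox_ml

    tumor_mask = np.zeros(spec.shape, bool)
    for m in tumor_masks:
        tumor_mask |= m
    liver_mask = liver >= 0.5
    masks = {
        "whole_liver": VoiMask(liver_mask, "whole_liver"),
        "tumor": VoiMask(tumor_mask & liver_mask, "tumor"),
        "healthy_liver": VoiMask(liver_mask & ~tumor_mask, "healthy_liver"),
    }
    grid = VoxelGrid(activity, (spacing,) * 3, origin, "MBq")
    m_t = float(activity[masks["tumor"].data].mean()) if masks["tumor"].voxel_count else 0.0
    m_h = float(activity[masks["healthy_liver"].data].mean())
    return {
        "activity": grid,
        "masks": masks,
        "true_tlr": m_t / m_h if m_h > 0 else float("nan"),
        "healthy_concentration_MBq_ml": c_healthy,
    }


def _shift_grid(grid: VoxelGrid, shift_mm, order: int) -> VoxelGrid:
    shift_vox = [m / s for m, s in zip(shift_mm, grid.spacing)]
    data = ndimage.shift(grid.data, shift_vox, order=order, mode="constant", cval=0.0)
    return grid.with_data(np.clip(data, 0.0, None))


def make_paired_study(
    spec: LiverStudySpec,
    model_a: AcquisitionModel,
    model_b: AcquisitionModel,
    administered_a: float = 190.0,  # MAA-like planning activity, MBq
    administered_b: float = 1000.0,  # Y-90 therapy activity, MBq
    patient_id: str = "synthetic",
) -> dict:
    """Simulate a planning/post-therapy pair sharing one anatomy.

    Study B's activity (and its masks) are rigidly translated by
    ``spec.misalignment`` before acquisition; the truth record carries the
    exact inverse transform and the true TLR measured on the activity grid.
    """
    base = rasterize_liver_study(spec, administered_a)
    act_a = base["activity"]
    act_b = base["activity"].with_data(base["activity"].data * (administered_b / administered_a))
    masks_b = dict(base["masks"])
    if any(m != 0 for m in spec.misalignment):
        act_b = _shift_grid(act_b, spec.misalignment, order=1)
        masks_b = {
            name: VoiMask(
                _shift_grid(
                    VoxelGrid(m.data.astype(float), act_b.spacing, act_b.origin),
                    spec.misalignment, order=0,
                ).data > 0.5,
                m.role, m.label,
            )
            for name, m in base["masks"].items()
        }
    study_a = StudySet(
        spect=simulate_acquisition(act_a, model_a),
        ct_masks=dict(base["masks"]),
        administered_activity=administered_a,
        agent="MAA",
        patient_id=patient_id,
    )
    study_b = StudySet(
        spect=simulate_acquisition(act_b, model_b),
        ct_masks=masks_b,
        administered_activity=administered_b,
        agent="Y90",
        patient_id=patient_id,
    )
    return {
        "study_a": study_a,
        "study_b": study_b,
        "truth": {
            "true_tlr": base["true_tlr"],
            "masks": base["masks"],
            "activity_a": act_a,
            "activity_b": act_b,
            "transform_mm": tuple(spec.misalignment),
            "inverse_transform_mm": tuple(-m for m in spec.misalignment),
        },
    }


def make_cohort(
    n: int = 12,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 48),
    tlr_range: tuple[float, float] = (2.0, 15.0),
    administered_range: tuple[float, float] = (550.0, 2100.0),
    noise: str = "poisson",
    psf_fwhm: float = 12.0,
    cf: float = 9049.0,
) -> list[dict]:
    """Seeded synthetic patient cohort of paired MAA/Y-90 studies.

    Administered therapy activities and true TLRs vary per patient across
    clinically plausible ranges; anatomy is jittered so studies are not
    copies of each other.  Returns :func:`make_paired_study` records.
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        mult = float(rng.uniform(*tlr_range))
        admin_b = float(rng.uniform(*administered_range))
        jitter = rng.uniform(-6, 6, size=3)
        axes = (
            float(rng.uniform(28, 36)),
            float(rng.uniform(22, 30)),
            float(rng.uniform(20, 26)),
        )
        spec = LiverStudySpec(
            tumors=[TumorSpec((35.0 + jitter[0], 15.0 + jitter[1], 5.0 + jitter[2]),
                              axes, uptake_multiplier=mult)],
            shape=shape,
        )
        model_a = AcquisitionModel(cf=cf, psf_fwhm=psf_fwhm, noise=noise,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        model_b = AcquisitionModel(cf=cf, psf_fwhm=psf_fwhm, noise=noise,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        case = make_paired_study(spec, model_a, model_b,
                                 administered_b=admin_b, patient_id=f"synth_{i + 1:02d}")
        case["truth"]["uptake_multiplier"] = mult
        cases.append(case)
    return cases
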