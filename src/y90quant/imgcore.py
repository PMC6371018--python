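"""Core image/mask data model, NIfTI I/O, resampling and VOI statistics.

All stages of the quantification pipeline share two containers: a
:class:`VoxelGrid` (3-D scalar lattice with voxel spacing, world origin and a
physical-units tag) and a :class:`VoiMask` (binary volume on the same lattice
with a semantic role such as ``tumor`` or ``background``).

Conventions
-----------
* Voxel indices are 0-based; the world coordinate of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (voxel-centred).
* The third array axis is the axial (z) direction.
* Masks must share the exact grid of their image — statistics never resample
  implicitly.
* Units tags are propagated and checked at every operation boundary; mixing
  e.g. cps and MBq raises :class:`UnitsError` instead of silently computing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VALID_UNITS",
    "MASK_ROLES",
    "UnitsError",
    "VoxelGrid",
    "VoiMask",
    "StudySet",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "resample_to",
    "voi_stats",
    "mask_difference",
]

#: Physical units a grid may carry.  ``cps`` — reconstructed count rate;
#: ``MBq`` — activity; ``MBq_s`` — cumulated (time-integrated) activity;
#: ``mGy``/``Gy`` — absorbed dose.
VALID_UNITS = frozenset({"cps", "MBq", "MBq_s", "mGy", "Gy", "unitless"})

MASK_ROLES = frozenset(
    {"tumor", "healthy_liver", "whole_liver", "sphere", "background", "body"}
)


class UnitsError(ValueError):
    """Raised when an operation receives a grid with the wrong units tag."""


@dataclass
class VoxelGrid:
    """3-D scalar image with geometry and a units tag.

    Parameters
    ----------
    data : ndarray
        Finite real values, shape ``(nx, ny, nz)``.
    spacing : tuple of float
        Per-axis voxel edge length in mm (all > 0).
    origin : tuple of float
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    units : str
        One of :data:`VALID_UNITS`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = "unitless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.units not in VALID_UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}; valid: {sorted(VALID_UNITS)}")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (spacing is in mm)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray, units: str | None = None) -> "VoxelGrid":
        """New grid with identical geometry and replaced voxel values."""
        return VoxelGrid(data, self.spacing, self.origin, units or self.units)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class VoiMask:
    """Binary volume-of-interest aligned to a companion :class:`VoxelGrid`."""

    data: np.ndarray
    role: str = "body"
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; valid: {sorted(MASK_ROLES)}")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "VoiMask") -> "VoiMask":
        return VoiMask(self.data & other.data, self.role, self.label)


@dataclass
class StudySet:
    """One acquisition (MAA-like planning or Y-90 post-therapy) plus its masks."""

    spect: VoxelGrid
    ct_masks: dict[str, VoiMask] = field(default_factory=dict)
    administered_activity: float = 0.0  # MBq
    agent: str = "Y90"  # "MAA" | "Y90"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.administered_activity < 0:
            raise ValueError("administered_activity must be >= 0")
        if self.agent not in {"MAA", "Y90"}:
            raise ValueError(f"agent must be 'MAA' or 'Y90', got {self.agent!r}")
        for name, m in self.ct_masks.items():
            if m.data.shape != self.spect.shape:
                raise ValueError(f"mask {name!r} not aligned to SPECT grid")


def require_units(grid: VoxelGrid, expected: str | Iterable[str]) -> None:
    allowed = {expected} if isinstance(expected, str) else set(expected)
    if grid.units not in allowed:
        raise UnitsError(f"expected units {sorted(allowed)}, got {grid.units!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_grid(path: str | Path, expected_units: str = "unitless") -> VoxelGrid:
    """Read a 3-D NIfTI volume into a :class:`VoxelGrid`.

    Spacing comes from the header zooms and the origin from the affine
    translation; the units tag is supplied by the caller (NIfTI carries no
    activity/dose units).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3-D volume, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path.name}: non-positive voxel spacing {spacing}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VoxelGrid(np.asarray(data, dtype=np.float64), spacing, origin, expected_units)


def write_grid(grid: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(grid.data.astype(np.float64), _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, role: str = "body", label: str = "") -> VoiMask:
    grid = read_grid(path, "unitless")
    return VoiMask(grid.data > 0, role, label)


def write_mask(mask: VoiMask, like: VoxelGrid, path: str | Path) -> None:
    """Write a mask as 0/1 unsigned 8-bit NIfTI on the geometry of ``like``."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(like.spacing, like.origin)
    )
    img.header.set_zooms(like.spacing)
    nib.save(img, str(path))


def read_dicom_series(directory: str | Path, expected_units: str = "unitless") -> VoxelGrid:
    """Convenience import of a single-frame DICOM series as a VoxelGrid.

    Slices are sorted by their z position; spacing is taken from
    ``PixelSpacing`` and the inter-slice distance.  Not intended as archival
    round-trip I/O — NIfTI is the canonical on-disk format.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in {".dcm", ""})
    datasets = [pydicom.dcmread(str(p)) for p in files if p.is_file()]
    datasets = [d for d in datasets if hasattr(d, "PixelData")]
    if not datasets:
        raise FileNotFoundError(f"no DICOM image files under {directory}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    arrs = []
    for d in datasets:
        a = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        inter = float(getattr(d, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    vol = np.stack(arrs, axis=-1)  # (row, col, slice)
    first = datasets[0]
    dr, dc = (float(x) for x in first.PixelSpacing)
    if len(datasets) > 1:
        dz = float(datasets[1].ImagePositionPatient[2]) - float(
            first.ImagePositionPatient[2]
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(x) for x in first.ImagePositionPatient)
    return VoxelGrid(vol, (dr, dc, abs(dz)), origin, expected_units)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def resample_to(src: VoxelGrid, ref: VoxelGrid, mode: str = "trilinear") -> VoxelGrid:
    """Resample ``src`` onto the lattice of ``ref``.

    ``trilinear`` preserves constant fields exactly; ``nearest`` preserves the
    value set (used for masks).  Sampling outside ``src`` clamps to the edge.
    """
    orders = {"nearest": 0, "trilinear": 1}
    if mode not in orders:
        raise ValueError(f"mode must be one of {sorted(orders)}, got {mode!r}")
    if min(ref.shape) < 1 or any(s <= 0 for s in ref.spacing):
        raise ValueError("degenerate reference geometry")
    idx = np.indices(ref.shape, dtype=np.float64)
    coords = [
        (ref.origin[ax] + idx[ax] * ref.spacing[ax] - src.origin[ax]) / src.spacing[ax]
        for ax in range(3)
    ]
    out = ndimage.map_coordinates(src.data, coords, order=orders[mode], mode="nearest")
    return VoxelGrid(out, ref.spacing, ref.origin, src.units)


def voi_stats(img: VoxelGrid, mask: VoiMask) -> dict[str, float]:
    """Mean, total, voxel count and volume (ml) of ``img`` inside ``mask``."""
    if mask.data.shape != img.shape:
        raise ValueError("mask not aligned to image grid")
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty mask")
    vals = img.data[mask.data]
    total = float(vals.sum())
    return {
        "mean": total / n,
        "total": total,
        "voxel_count": n,
        "volume_ml": n * img.voxel_volume_ml,
    }


def mask_difference(whole: VoiMask, part: VoiMask, role: str | None = None) -> VoiMask:
    """Set difference ``whole \\ part`` (e.g. whole liver minus tumor)."""
    if whole.data.shape != part.data.shape:
        raise ValueError("mask shapes differ")
    return VoiMask(whole.data & ~part.data, role or whole.role, whole.label)
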