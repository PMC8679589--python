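"""SUV volumes, voxel masks and geometric primitives.

The common substrate of the pipeline is a 3-D grid of standardized uptake
values (SUV, dimensionless g/mL convention) with physical voxel spacing.
Conventions, stated once and used everywhere:

* axis order is (x, y, z) with z the cranio-caudal axis;
* voxel indices are 0-based and the world position of voxel ``(i, j, k)`` is
  ``origin + index * spacing`` (millimetres), i.e. the voxel *center*;
* a voxel belongs to a geometric region (sphere, cylinder, ellipsoid) iff its
  center lies inside the region — a deterministic rule that makes every mask
  in this package bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import EmptyRegionError, InvalidMetadataError, OutOfBoundsError

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"expected a scalar or length-3 sequence, got {x!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class InjectionMeta:
    """Tracer injection metadata needed to convert activity maps to SUV.

    Parameters
    ----------
    injected_dose_mbq : float
        Injected activity at injection time, MBq.
    body_weight_kg : float
        Patient body weight, kg.
    uptake_interval_min : float
        Minutes between injection and acquisition.
    half_life_min : float
        Isotope half-life in minutes; defaults to fluorine-18.
    """

    injected_dose_mbq: float
    body_weight_kg: float
    uptake_interval_min: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("injected_dose_mbq", "body_weight_kg", "half_life_min"):
            if not getattr(self, name) > 0:
                raise InvalidMetadataError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.uptake_interval_min < 0:
            raise InvalidMetadataError("uptake_interval_min must be >= 0")

    @property
    def decayed_dose_kbq(self) -> float:
        """Injected dose decay-corrected to acquisition time, in kBq (base-2 decay)."""
        return self.injected_dose_mbq * 1000.0 * 2.0 ** (-self.uptake_interval_min / self.half_life_min)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InjectionMeta":
        return cls(**json.loads(Path(path).read_text()))


class _Grid:
    """Shared grid bookkeeping for volumes and masks."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def _init_grid(self, spacing, origin) -> None:
        spacing = _as_triple(spacing)
        if not all(s > 0 for s in spacing):
            raise ValueError(f"all spacing components must be > 0, got {spacing}")
        self.spacing = spacing
        self.origin = _as_triple(origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """World (mm) coordinates of voxel center(s); index may be (N, 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel index of world coordinates (mm)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "_Grid") -> bool:
        return (
            getattr(self, "shape", None) == getattr(other, "shape", None)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def _affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


class SUVVolume(_Grid):
    """A 3-D SUV image with physical spacing.

    ``values`` is a float64 array indexed ``[x, y, z]``; all values must be
    finite and non-negative (SUV is a ratio of concentrations).
    """

    def __init__(self, values: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV values must all be finite")
        if np.any(values < 0):
            raise ValueError("SUV values must be >= 0")
        self.values = values
        self._init_grid(spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self._affine())

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "SUVVolume":
        img = nib.load(str(path))
        spacing = [float(z) for z in img.header.get_zooms()[:3]]
        origin = img.affine[:3, 3]
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


class VoxelMask(_Grid):
    """A boolean voxel set congruent with an :class:`SUVVolume` grid."""

    def __init__(self, data: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {data.shape}")
        self.data = data.astype(bool)
        self._init_grid(spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def like(self, data: np.ndarray) -> "VoxelMask":
        """A new mask on this mask's grid."""
        return VoxelMask(data, self.spacing, self.origin)

    @classmethod
    def empty_like(cls, vol: _Grid) -> "VoxelMask":
        return cls(np.zeros(vol.shape, dtype=bool), vol.spacing, vol.origin)

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        return self.like(self.data & other.data)

    def __or__(self, other: "VoxelMask") -> "VoxelMask":
        return self.like(self.data | other.data)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self._affine()), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelMask":
        img = nib.load(str(path))
        spacing = [float(z) for z in img.header.get_zooms()[:3]]
        return cls(np.asarray(img.dataobj) > 0, spacing, img.affine[:3, 3])


def suv_from_activity(
    concentration_kbq_ml: np.ndarray,
    meta: InjectionMeta,
    spacing,
    origin=(0.0, 0.0, 0.0),
) -> SUVVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    SUV normalizes tissue concentration by injected dose per body weight:
    ``SUV = conc / (decayed_dose_kBq / body_weight_g)``, with the dose
    decay-corrected over the uptake interval. Under the g/mL convention the
    result is dimensionless.
    """
    conc = np.asarray(concentration_kbq_ml, dtype=np.float64)
    if not np.all(np.isfinite(conc)) or np.any(conc < 0):
        raise ValueError("activity concentration must be finite and >= 0")
    ratio = meta.decayed_dose_kbq / (meta.body_weight_kg * 1000.0)  # kBq per g
    return SUVVolume(conc / ratio, spacing, origin)


def mask_volume_cm3(mask: VoxelMask) -> float:
    """Physical volume of a mask in cm^3 (0 for an empty mask)."""
    return mask.volume_cm3


def sphere_radius_mm(target_volume_cm3: float) -> float:
    """Radius of a sphere of the given volume: r = (3V / 4 pi)^(1/3)."""
    return float((3.0 * target_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _voxel_center_grids(vol: _Grid):
    axes = [vol.origin[a] + np.arange(vol.shape[a]) * vol.spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def sphere_mask(vol: _Grid, center_mm, target_volume_cm3: float) -> tuple[VoxelMask, bool]:
    """Voxels whose centers lie within a sphere of the given physical volume.

    Returns ``(mask, clipped)`` where ``clipped`` is True when the sphere
    extends beyond the grid (the mask is then truncated at the edge).
    """
    center = np.asarray(_as_triple(center_mm))
    idx = vol.world_to_index(center)
    if np.any(idx < -0.5) or np.any(idx > np.asarray(vol.shape) - 0.5):
        raise OutOfBoundsError(f"sphere center {center_mm} outside grid")
    r = sphere_radius_mm(target_volume_cm3)
    gx, gy, gz = _voxel_center_grids(vol)
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    data = d2 <= r * r
    lo = vol.index_to_world((0, 0, 0))
    hi = vol.index_to_world(np.asarray(vol.shape) - 1)
    clipped = bool(np.any(center - r < lo) or np.any(center + r > hi))
    return VoxelMask(data, vol.spacing, vol.origin), clipped


def cylinder_mask(vol: _Grid, center_mm, diameter_mm: float, length_mm: float, axis: int = 2) -> VoxelMask:
    """Voxels inside a finite cylinder aligned with a grid axis (default z).

    A voxel is inside iff its center is within ``diameter/2`` of the cylinder
    axis and within ``length/2`` of the center plane. Degenerate sizes still
    include at least the voxel nearest the center.
    """
    center = np.asarray(_as_triple(center_mm))
    idx = vol.world_to_index(center)
    if np.any(idx < -0.5) or np.any(idx > np.asarray(vol.shape) - 0.5):
        raise OutOfBoundsError(f"cylinder center {center_mm} outside grid")
    grids = _voxel_center_grids(vol)
    radial_axes = [a for a in range(3) if a != axis]
    d2 = sum((grids[a] - center[a]) ** 2 for a in radial_axes)
    axial = np.abs(grids[axis] - center[axis])
    data = (d2 <= (diameter_mm / 2.0) ** 2) & (axial <= length_mm / 2.0)
    if not data.any():
        # degenerate cylinder smaller than one voxel: include the nearest voxel
        nearest = tuple(int(np.clip(round(idx[a]), 0, vol.shape[a] - 1)) for a in range(3))
        data = np.zeros(vol.shape, dtype=bool)
        data[nearest] = True
    mask = VoxelMask(data, vol.spacing, vol.origin)
    if mask.n_voxels == 0:
        raise EmptyRegionError("cylinder does not intersect the grid")
    return mask
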