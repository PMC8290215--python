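"""Voxel-grid data model and binary mask algebra.

All images and masks in the pipeline live on a regular 3-D voxel grid with
anisotropic spacing in millimetres. A voxel's stored value represents its
centre; indices are 0-based; every physical distance is computed in mm
using the per-axis spacing. Two objects are *co-registered* iff shape,
spacing and origin match exactly — the pipeline refuses mixed geometries
rather than silently resampling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Unit",
    "Role",
    "Grid",
    "ImageVolume",
    "StructureMask",
    "GeometryError",
    "UnitError",
    "is_coregistered",
    "require_coregistered",
    "volume_cc",
    "boolean_op",
    "mask_and",
    "mask_or",
    "mask_minus",
]


class GeometryError(ValueError):
    """Raised when grids that must be co-registered are not."""


class UnitError(ValueError):
    """Raised when an operation receives a volume with the wrong unit tag."""


class Unit(str, enum.Enum):
    """Physical unit carried by an :class:`ImageVolume`."""

    ACTIVITY_KBQ_PER_ML = "activity_kBq_per_mL"
    SUV = "SUV"
    GY = "Gy"
    ARBITRARY = "arbitrary"


class Role(str, enum.Enum):
    """Clinical role of a :class:`StructureMask`."""

    GTV = "GTV"
    BTV = "BTV"
    CTV = "CTV"
    PTV = "PTV"
    BASAL_GANGLIA = "BASAL_GANGLIA"
    BARRIER = "BARRIER"
    RECURRENCE = "RECURRENCE"
    BRAIN = "BRAIN"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel grid: shape, spacing (mm) and origin (mm).

    The origin is the physical position of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GeometryError("grid shape, spacing and origin must be 3-D")
        if any(s <= 0 for s in self.shape):
            raise GeometryError(f"non-positive grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis], dtype=float)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable physical coordinate arrays (x, y, z) of voxel centres."""
        x = self.axis_coords_mm(0)[:, None, None]
        y = self.axis_coords_mm(1)[None, :, None]
        z = self.axis_coords_mm(2)[None, None, :]
        return x, y, z

    def index_of_mm(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel whose centre is nearest to a physical point."""
        idx = []
        for a in range(3):
            i = int(round((float(point_mm[a]) - self.origin[a]) / self.spacing[a]))
            idx.append(min(max(i, 0), self.shape[a] - 1))
        return tuple(idx)

    def center_mm(self) -> tuple[float, float, float]:
        """Physical centre of the grid's bounding box."""
        return tuple(
            self.origin[a] + self.spacing[a] * (self.shape[a] - 1) / 2.0 for a in range(3)
        )


def _as_grid(shape, spacing, origin) -> Grid:
    return Grid(tuple(shape), tuple(spacing), tuple(origin))


@dataclass
class ImageVolume:
    """A 3-D scalar field on a voxel grid with an explicit unit tag.

    Houses PET activity or SUV images and dose grids. All voxel values must
    be finite; the unit tag lets downstream operations reject e.g. raw
    activity where SUV is required.
    """

    data: np.ndarray
    grid: Grid
    unit: Unit = Unit.ARBITRARY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"image payload must be 3-D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.grid.shape:
            raise GeometryError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite voxel values")
        self.unit = Unit(self.unit)

    @classmethod
    def from_array(cls, data, spacing, origin=(0.0, 0.0, 0.0), unit=Unit.ARBITRARY) -> "ImageVolume":
        data = np.asarray(data, dtype=float)
        return cls(data, _as_grid(data.shape, spacing, origin), unit)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    def with_data(self, data, unit: Unit | None = None) -> "ImageVolume":
        return ImageVolume(np.asarray(data, dtype=float), self.grid, unit or self.unit)

    def require_unit(self, unit: Unit, what: str = "operation") -> None:
        if self.unit is not Unit(unit):
            raise UnitError(f"{what} requires unit {Unit(unit).value}, got {self.unit.value}")


@dataclass
class StructureMask:
    """A binary structure (GTV, BTV, ...) on a voxel grid."""

    data: np.ndarray
    grid: Grid
    role: Role = Role.OTHER
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"mask payload must be 3-D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        self.role = Role(self.role)

    @classmethod
    def from_array(cls, data, spacing, origin=(0.0, 0.0, 0.0), role=Role.OTHER, label="") -> "StructureMask":
        data = np.asarray(data).astype(bool)
        return cls(data, _as_grid(data.shape, spacing, origin), role, label)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def with_data(self, data, role: Role | None = None, label: str | None = None) -> "StructureMask":
        return StructureMask(
            np.asarray(data).astype(bool),
            self.grid,
            role if role is not None else self.role,
            label if label is not None else self.label,
        )


def is_coregistered(a, b) -> bool:
    """True iff two grid-bearing objects share shape, spacing and origin exactly."""
    ga = a if isinstance(a, Grid) else a.grid
    gb = b if isinstance(b, Grid) else b.grid
    return ga.shape == gb.shape and ga.spacing == gb.spacing and ga.origin == gb.origin


def require_coregistered(*objs) -> Grid:
    """Assert pairwise co-registration and return the shared grid."""
    if not objs:
        raise ValueError("no objects given")
    grids = [o if isinstance(o, Grid) else o.grid for o in objs]
    ref = grids[0]
    for g in grids[1:]:
        if not (g.shape == ref.shape and g.spacing == ref.spacing and g.origin == ref.origin):
            raise GeometryError(
                "inputs are not co-registered: "
                f"{ref.shape}/{ref.spacing}/{ref.origin} vs {g.shape}/{g.spacing}/{g.origin}"
            )
    return ref


def volume_cc(mask: StructureMask) -> float:
    """Volume of a mask in cm³ (voxel count × voxel volume / 1000)."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3 / 1000.0


_BOOL_OPS = {
    "and": np.logical_and,
    "or": np.logical_or,
    "minus": lambda a, b: np.logical_and(a, np.logical_not(b)),
}


def boolean_op(a: StructureMask, b: StructureMask, op: str, role: Role = Role.OTHER,
               label: str = "") -> StructureMask:
    """Voxelwise boolean combination of two co-registered masks.

    ``op`` is one of ``and`` (intersection), ``or`` (union), ``minus``
    (set difference a\\b). The result's role defaults to OTHER.
    """
    require_coregistered(a, b)
    try:
        fn = _BOOL_OPS[op]
    except KeyError:
        raise ValueError(f"unknown boolean op {op!r}; expected one of {sorted(_BOOL_OPS)}") from None
    return StructureMask(fn(a.data, b.data), a.grid, role, label)


def mask_and(a: StructureMask, b: StructureMask, **kw) -> StructureMask:
    return boolean_op(a, b, "and", **kw)


def mask_or(a: StructureMask, b: StructureMask, **kw) -> StructureMask:
    return boolean_op(a, b, "or", **kw)


def mask_minus(a: StructureMask, b: StructureMask, **kw) -> StructureMask:
    return boolean_op(a, b, "minus", **kw)
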