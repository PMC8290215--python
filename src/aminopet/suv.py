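"""SUV quantification: body-weight normalisation, decay correction, sphere ROIs.

The standardized uptake value by the body-weight method is

    SUV(v) = c(v) / ( A_acq / (m × 1000) )

with c the activity concentration in kBq/mL, A_acq the injected activity
decay-corrected to acquisition time (kBq), and m the patient weight in kg;
tissue density is taken as 1 g/mL so weight in kg converts to volume in mL.
Physical decay of the ¹⁸F label (half-life 109.77 min) is handled by
:func:`decay_factor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .grids import Grid, ImageVolume, Role, StructureMask, Unit, require_coregistered

__all__ = [
    "F18_HALF_LIFE_MIN",
    "AcquisitionMeta",
    "RoiStats",
    "decay_factor",
    "compute_suv",
    "place_sphere_roi",
    "roi_stats",
    "EmptyRoiError",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


class EmptyRoiError(ValueError):
    """Raised when a region of interest contains no voxels."""


def decay_factor(dt_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Decay-correction factor 2^(dt/T½) for a signal measured ``dt_min`` later.

    Multiplying a signal acquired ``dt_min`` minutes after the reference time
    by this factor corrects it back to the reference time; ``dt_min`` may be
    negative (correction forward in time). ``decay_factor(0) == 1``.
    """
    dt_min = float(dt_min)
    if not np.isfinite(dt_min):
        raise ValueError(f"elapsed time must be finite, got {dt_min}")
    if not (half_life_min > 0):
        raise ValueError(f"half-life must be positive, got {half_life_min}")
    return float(2.0 ** (dt_min / half_life_min))


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection/acquisition bookkeeping needed for SUV-bw computation."""

    injected_activity_MBq: float
    patient_weight_kg: float
    t_injection: datetime
    t_acquisition: datetime
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if not (self.injected_activity_MBq > 0):
            raise ValueError(f"injected activity must be positive, got {self.injected_activity_MBq}")
        if not (self.patient_weight_kg > 0):
            raise ValueError(f"patient weight must be positive, got {self.patient_weight_kg}")
        if not (self.half_life_min > 0):
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")
        if self.t_acquisition < self.t_injection:
            raise ValueError("acquisition time precedes injection time")

    @property
    def uptake_min(self) -> float:
        """Minutes elapsed between injection and acquisition."""
        return (self.t_acquisition - self.t_injection).total_seconds() / 60.0

    def activity_at_acquisition_MBq(self) -> float:
        """Injected activity decayed forward to the acquisition time."""
        return self.injected_activity_MBq / decay_factor(self.uptake_min, self.half_life_min)

    def to_dict(self) -> dict:
        return {
            "injected_activity_MBq": self.injected_activity_MBq,
            "patient_weight_kg": self.patient_weight_kg,
            "t_injection": self.t_injection.isoformat(),
            "t_acquisition": self.t_acquisition.isoformat(),
            "half_life_min": self.half_life_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(
            injected_activity_MBq=float(d["injected_activity_MBq"]),
            patient_weight_kg=float(d["patient_weight_kg"]),
            t_injection=datetime.fromisoformat(d["t_injection"]),
            t_acquisition=datetime.fromisoformat(d["t_acquisition"]),
            half_life_min=float(d.get("half_life_min", F18_HALF_LIFE_MIN)),
        )


def compute_suv(activity: ImageVolume, meta: AcquisitionMeta) -> ImageVolume:
    """Convert an activity-concentration image (kBq/mL) to SUV (body weight).

    The injected activity is decay-corrected from injection to acquisition
    time before the division, so a uniform concentration equal to
    A_acq/(weight×1000) maps to SUV 1 everywhere.
    """
    activity.require_unit(Unit.ACTIVITY_KBQ_PER_ML, "compute_suv")
    a_kbq = meta.activity_at_acquisition_MBq() * 1000.0
    denom = a_kbq / (meta.patient_weight_kg * 1000.0)  # kBq/mL at uniform distribution
    return activity.with_data(activity.data / denom, unit=Unit.SUV)


def place_sphere_roi(grid: Grid, center_mm, diameter_mm: float = 10.0,
                     role: Role = Role.OTHER, label: str = "ROI") -> StructureMask:
    """Spherical ROI: voxels whose centre lies within diameter/2 of a point.

    The boundary is inclusive (distance exactly equal to the radius counts).
    Default diameter 10 mm matches the standard reference ROI used for the
    tumour site and the contralateral centrum-semiovale white matter.
    """
    if not (diameter_mm > 0):
        raise ValueError(f"ROI diameter must be positive, got {diameter_mm}")
    cx, cy, cz = (float(c) for c in center_mm)
    x, y, z = grid.coords_mm()
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    inside = r2 <= (diameter_mm / 2.0) ** 2
    if not inside.any():
        raise EmptyRoiError(
            f"sphere ROI (d={diameter_mm} mm at {tuple(center_mm)}) contains no voxel centre"
        )
    return StructureMask(inside, grid, role, label)


@dataclass(frozen=True)
class RoiStats:
    """Summary statistics of an SUV image over an ROI."""

    mean: float
    max: float
    voxel_count: int
    center_mm: tuple[float, float, float]


def roi_stats(suv: ImageVolume, roi: StructureMask) -> RoiStats:
    """Mean and max SUV over the voxels of an ROI."""
    require_coregistered(suv, roi)
    if roi.is_empty():
        raise EmptyRoiError("ROI is empty")
    vals = suv.data[roi.data]
    idx = np.argwhere(roi.data).mean(axis=0)
    center = tuple(
        float(suv.grid.origin[a] + suv.grid.spacing[a] * idx[a]) for a in range(3)
    )
    return RoiStats(mean=float(vals.mean()), max=float(vals.max()),
                    voxel_count=int(vals.size), center_mm=center)
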