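"""Concordance and coverage metrics between target volumes.

Implements the directed 95th-percentile Hausdorff distance (HD95) from one
structure's surface to another's, the supplementary-volume-contour (SVC)
distances that quantify how far a PET-defined volume extends beyond the
MRI-defined GTV, within/outside volume decomposition, isodose coverage
fractions, and recurrence-overlap analysis.

Conventions (fixed for reproducibility):

* surfaces are mask voxels with at least one 6-connected face neighbour
  outside the mask (voxels at the grid edge count as surface);
* distances are Euclidean, between voxel centres, in physical mm;
* HD95 is taken from source-surface voxels to the nearest target-surface
  voxel; the percentile uses linear interpolation between order statistics;
* SVC distances are measured from every voxel of BTV minus GTV (not only the
  surface) to the nearest GTV surface voxel, so the mean reflects how far
  the supplementary volume extends;
* isodose comparison is inclusive (dose >= iso_fraction × prescription).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import (
    ImageVolume,
    Role,
    StructureMask,
    Unit,
    mask_and,
    mask_minus,
    require_coregistered,
    volume_cc,
)

__all__ = [
    "ConcordanceReport",
    "CoverageReport",
    "surface_voxels",
    "hd95_directed",
    "svc_distances",
    "overlap_decomposition",
    "concordance",
    "dice",
    "dose_coverage",
    "recurrence_analysis",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask: StructureMask) -> StructureMask:
    """Mask voxels with at least one face neighbour outside the mask."""
    if mask.is_empty():
        raise ValueError("mask is empty; it has no surface")
    interior = ndimage.binary_erosion(mask.data, structure=_FACE_STRUCT, border_value=0)
    return mask.with_data(mask.data & ~interior)


def _points_mm(mask: StructureMask) -> np.ndarray:
    idx = np.argwhere(mask.data).astype(float)
    spacing = np.asarray(mask.grid.spacing)
    origin = np.asarray(mask.grid.origin)
    return idx * spacing + origin


def _nearest_surface_distances(points_mm: np.ndarray, target: StructureMask) -> np.ndarray:
    tree = cKDTree(_points_mm(surface_voxels(target)))
    d, _ = tree.query(points_mm, k=1)
    return np.atleast_1d(d)


def hd95_directed(source: StructureMask, target: StructureMask,
                  percentile: float = 95.0) -> float:
    """Directed percentile Hausdorff distance (mm) from source to target.

    The given percentile (default 95) of the nearest-point distances from
    every surface voxel of ``source`` to the surface of ``target``. Not
    symmetrised: hd95(A, B) generally differs from hd95(B, A).
    """
    require_coregistered(source, target)
    if source.is_empty() or target.is_empty():
        raise ValueError("hd95 requires two non-empty masks")
    d = _nearest_surface_distances(_points_mm(surface_voxels(source)), target)
    return float(np.percentile(d, percentile))


def svc_distances(gtv: StructureMask, btv: StructureMask) -> tuple[float, float]:
    """Max and mean distance (mm) of the supplementary volume from the GTV.

    The supplementary volume contour is BTV minus GTV; distances run from
    each of its voxels to the nearest GTV surface voxel. Returns (0, 0)
    when the BTV adds nothing beyond the GTV.
    """
    require_coregistered(gtv, btv)
    if gtv.is_empty():
        raise ValueError("GTV is empty")
    svc = btv.data & ~gtv.data
    if not svc.any():
        return 0.0, 0.0
    pts = _points_mm(btv.with_data(svc))
    d = _nearest_surface_distances(pts, gtv)
    return float(d.max()), float(d.mean())


@dataclass(frozen=True)
class ConcordanceReport:
    """Distance and volume agreement between a BTV and the GTV."""

    hd95_mm: float
    svc_max_mm: float
    svc_mean_mm: float
    total_cc: float
    within_cc: float
    outside_cc: float
    outside_fraction: float


def overlap_decomposition(btv: StructureMask, gtv: StructureMask) -> tuple[float, float, float, float]:
    """(total, within, outside) volumes in cm³ and the outside fraction.

    ``within`` is BTV∩GTV, ``outside`` BTV∖GTV; they sum to the BTV total
    exactly (voxel arithmetic). The fraction is 0 for an empty BTV.
    """
    require_coregistered(btv, gtv)
    total = volume_cc(btv)
    within = volume_cc(mask_and(btv, gtv))
    # difference rather than an independent product: keeps the conservation
    # identity within + outside == total exact in float arithmetic
    outside = total - within
    n_total = btv.voxel_count
    n_outside = int(np.count_nonzero(btv.data & ~gtv.data))
    fraction = (n_outside / n_total) if n_total else 0.0
    return total, within, outside, fraction


def concordance(gtv: StructureMask, btv: StructureMask) -> ConcordanceReport:
    """Full GTV↔BTV concordance report (HD95 directed GTV→BTV, SVC, volumes)."""
    total, within, outside, fraction = overlap_decomposition(btv, gtv)
    hd = hd95_directed(gtv, btv)
    svc_max, svc_mean = svc_distances(gtv, btv)
    return ConcordanceReport(hd95_mm=hd, svc_max_mm=svc_max, svc_mean_mm=svc_mean,
                             total_cc=total, within_cc=within, outside_cc=outside,
                             outside_fraction=fraction)


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice overlap coefficient of two masks (1 for two empty masks)."""
    require_coregistered(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


@dataclass(frozen=True)
class CoverageReport:
    """Fraction of a structure receiving at least an isodose level."""

    covered_fraction: float
    iso_level_Gy: float
    prescription_Gy: float


def dose_coverage(dose: ImageVolume, mask: StructureMask, prescription_Gy: float,
                  iso_fraction: float = 0.95) -> CoverageReport:
    """Fraction of mask voxels with dose >= iso_fraction × prescription."""
    dose.require_unit(Unit.GY, "dose_coverage")
    require_coregistered(dose, mask)
    if not (prescription_Gy > 0):
        raise ValueError(f"prescription must be positive, got {prescription_Gy}")
    if mask.is_empty():
        raise ValueError("structure mask is empty")
    iso = iso_fraction * prescription_Gy
    covered = int(np.count_nonzero(dose.data[mask.data] >= iso))
    return CoverageReport(covered_fraction=covered / mask.voxel_count,
                          iso_level_Gy=iso, prescription_Gy=prescription_Gy)


def recurrence_analysis(rec: StructureMask,
                        references: Mapping[str, StructureMask]) -> dict[str, float]:
    """Fraction of the recurrence volume outside each reference structure."""
    if rec.is_empty():
        raise ValueError("recurrence mask is empty")
    out: dict[str, float] = {}
    n = rec.voxel_count
    for name, ref in references.items():
        require_coregistered(rec, ref)
        outside = int(np.count_nonzero(rec.data & ~ref.data))
        out[str(name)] = outside / n
    return out
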