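"""Synthetic digital-patient generator with analytic ground truth.

Produces a co-registered set of volumes emulating an amino-acid PET study of
a glioblastoma patient: a brain-shaped (ellipsoidal) background with uniform
white-matter uptake, high-uptake basal-ganglia blobs (the physiological
FDOPA signal that must be excluded from tumour segmentation), a tumour whose
tracer-avid extent (infiltration) exceeds its contrast-enhancing core (the
GTV surrogate), a geometric dose distribution covering the PTV, and an
optional recurrence lesion with a designed overlap fraction.

Tumour uptake profiles are radially symmetric analytic functions, so the
iso-contour of any tumour-to-normal ratio — hence the true BTV and its
volume — is known in closed form. That is what makes parameter-recovery
testing of the whole pipeline possible.

All centres are specified as offsets in mm from the physical centre of the
grid (which is also the brain centre).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .grids import Grid, ImageVolume, Role, StructureMask, Unit, volume_cc
from .margins import MarginPolicy, build_targets

__all__ = [
    "TumorSpec",
    "BasalGangliaSpec",
    "BarrierSpec",
    "RecurrenceSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomResult",
    "generate_phantom",
    "make_recurrence",
    "save_phantom",
]

Profile = Literal["step", "radial_linear", "radial_gaussian"]


@dataclass(frozen=True)
class TumorSpec:
    """Tumour geometry and uptake profile.

    The enhancement radius models the contrast-enhancing core seen on T1CE
    MRI (the GTV); the infiltration radius is the larger tracer-avid extent.
    The T/N profile equals ``peak_tn_ratio`` at the centre and decays to 1
    (background) at the infiltration radius:

    * ``step``            — peak everywhere inside the infiltration radius;
    * ``radial_linear``   — tn(r) = peak − (peak−1)·r/R;
    * ``radial_gaussian`` — tn(r) = 1 + (peak−1)·exp(−r²/2σ²), σ = R/3,
      truncated to background beyond R.
    """

    center_offset_mm: tuple[float, float, float] = (-25.0, -35.0, 5.0)
    enhancement_radius_mm: float = 22.0
    infiltration_radius_mm: float = 35.0
    peak_tn_ratio: float = 3.8
    profile: Profile = "radial_linear"

    def __post_init__(self) -> None:
        if self.infiltration_radius_mm < self.enhancement_radius_mm:
            raise ValueError("infiltration radius must be >= enhancement radius")
        if not (self.peak_tn_ratio > 1):
            raise ValueError("peak T/N ratio must exceed 1")
        if self.profile not in ("step", "radial_linear", "radial_gaussian"):
            raise ValueError(f"unknown profile {self.profile!r}")

    def tn_at_radius(self, r) -> np.ndarray:
        """Tumour-to-normal ratio at radial distance r (mm) from the centre."""
        r = np.asarray(r, dtype=float)
        R, peak = self.infiltration_radius_mm, self.peak_tn_ratio
        if self.profile == "step":
            tn = np.where(r <= R, peak, 1.0)
        elif self.profile == "radial_linear":
            tn = np.where(r <= R, peak - (peak - 1.0) * r / R, 1.0)
        else:  # radial_gaussian
            sigma = R / 3.0
            tn = np.where(r <= R, 1.0 + (peak - 1.0) * np.exp(-(r ** 2) / (2.0 * sigma ** 2)), 1.0)
        return tn

    def iso_radius_mm(self, ratio: float) -> float:
        """Radius of the T/N = ratio iso-surface (closed form per profile)."""
        R, peak = self.infiltration_radius_mm, self.peak_tn_ratio
        if not (1.0 < ratio <= peak):
            raise ValueError(f"iso-surface defined only for ratios in (1, {peak}], got {ratio}")
        if self.profile == "step":
            return R
        if self.profile == "radial_linear":
            return R * (peak - ratio) / (peak - 1.0)
        sigma = R / 3.0
        return min(R, sigma * float(np.sqrt(2.0 * np.log((peak - 1.0) / (ratio - 1.0)))))


@dataclass(frozen=True)
class BasalGangliaSpec:
    """A spherical high-uptake physiological blob (FDOPA striatal uptake)."""

    center_offset_mm: tuple[float, float, float]
    radius_mm: float = 11.0
    tn_ratio: float = 2.2


@dataclass(frozen=True)
class BarrierSpec:
    """An axis-aligned slab acting as an anatomical barrier to CTV expansion."""

    axis: int
    position_offset_mm: float
    thickness_mm: float = 4.0


@dataclass(frozen=True)
class RecurrenceSpec:
    """A recurrence lesion with a designed fraction outside a reference role."""

    center_offset_mm: tuple[float, float, float] = (-25.0, -35.0, 5.0)
    radius_mm: float = 10.0
    designed_outside_fraction: float = 0.3
    vs_role: Role = Role.GTV

    def __post_init__(self) -> None:
        if not (0.0 <= self.designed_outside_fraction <= 1.0):
            raise ValueError("designed outside fraction must lie in [0, 1]")


def _default_basal_ganglia() -> tuple[BasalGangliaSpec, ...]:
    return (
        BasalGangliaSpec(center_offset_mm=(24.0, 15.0, 0.0)),
        BasalGangliaSpec(center_offset_mm=(-24.0, 15.0, 0.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """All ground-truth parameters of the synthetic patient.

    Defaults give a 128³ grid at 2 mm isotropic spacing with a tumour whose
    infiltration (35 mm) clearly exceeds its enhancement core (22 mm) —
    yielding GTV ≈ 45 cm³, in the middle of the volume range typical of
    glioblastoma cohorts, with both the T/N 1.7 and 2.0 iso-surfaces
    (26.3 / 22.5 mm at peak 3.8) beyond the enhancement radius — 5 %
    multiplicative noise, a 4 mm FWHM scanner PSF, and a 60 Gy prescription
    with 20 mm CTV and 3 mm PTV margins.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes_mm: tuple[float, float, float] = (75.0, 90.0, 70.0)
    background_suv: float = 1.0
    basal_ganglia: tuple[BasalGangliaSpec, ...] = field(default_factory=_default_basal_ganglia)
    tumor: TumorSpec = field(default_factory=TumorSpec)
    barriers: tuple[BarrierSpec, ...] = ()
    noise_sigma_fraction: float = 0.05
    psf_fwhm_mm: float = 4.0
    prescription_Gy: float = 60.0
    dose_falloff_mm: float = 5.0
    ctv_margin_mm: float = 20.0
    ptv_margin_mm: float = 3.0
    recurrence: Optional[RecurrenceSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.background_suv > 0):
            raise ValueError("background SUV must be positive")
        if self.noise_sigma_fraction < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise and PSF parameters must be non-negative")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.recurrence is not None:
            d["recurrence"]["vs_role"] = self.recurrence.vs_role.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "tumor" in d and isinstance(d["tumor"], dict):
            d["tumor"] = TumorSpec(**{k: tuple(v) if k == "center_offset_mm" else v
                                      for k, v in d["tumor"].items()})
        if "basal_ganglia" in d:
            d["basal_ganglia"] = tuple(
                BasalGangliaSpec(**{k: tuple(v) if k == "center_offset_mm" else v
                                    for k, v in b.items()}) if isinstance(b, dict) else b
                for b in d["basal_ganglia"]
            )
        if "barriers" in d:
            d["barriers"] = tuple(BarrierSpec(**b) if isinstance(b, dict) else b
                                  for b in d["barriers"])
        if d.get("recurrence") is not None and isinstance(d["recurrence"], dict):
            r = dict(d["recurrence"])
            r["vs_role"] = Role(r.get("vs_role", "GTV"))
            if "center_offset_mm" in r:
                r["center_offset_mm"] = tuple(r["center_offset_mm"])
            d["recurrence"] = RecurrenceSpec(**r)
        for k in ("shape", "spacing", "brain_semiaxes_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _radius_field(grid: Grid, center_mm) -> np.ndarray:
    x, y, z = grid.coords_mm()
    cx, cy, cz = center_mm
    return np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)


def _abs_center(grid: Grid, offset_mm) -> tuple[float, float, float]:
    c = grid.center_mm()
    return tuple(c[a] + float(offset_mm[a]) for a in range(3))


def _brain_mask(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    x, y, z = grid.coords_mm()
    cx, cy, cz = grid.center_mm()
    ax, ay, az = spec.brain_semiaxes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _tumor_tn_field(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    r = _radius_field(grid, _abs_center(grid, spec.tumor.center_offset_mm))
    return spec.tumor.tn_at_radius(r)


def _basal_ganglia_fields(spec: PhantomSpec, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """(T/N field, union mask) of the basal-ganglia blobs."""
    tn = np.ones(grid.shape)
    union = np.zeros(grid.shape, dtype=bool)
    for blob in spec.basal_ganglia:
        r = _radius_field(grid, _abs_center(grid, blob.center_offset_mm))
        inside = r <= blob.radius_mm
        tn = np.where(inside, np.maximum(tn, blob.tn_ratio), tn)
        union |= inside
    return tn, union


def _barrier_mask(spec: PhantomSpec, grid: Grid) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=bool)
    for b in spec.barriers:
        coords = grid.axis_coords_mm(b.axis)
        center = grid.center_mm()[b.axis] + b.position_offset_mm
        sel = np.abs(coords - center) <= b.thickness_mm / 2.0
        sl = [slice(None)] * 3
        sl[b.axis] = sel
        out[tuple(sl)] = True
    return out


@dataclass
class GroundTruth:
    """Closed-form bookkeeping of everything the phantom was built from."""

    spec: PhantomSpec
    grid: Grid
    brain_cc: float
    gtv_cc: float
    recurrence_outside_fraction: Optional[float] = None

    def iso_radius_mm(self, ratio: float) -> float:
        """Radius of the true T/N iso-surface of the tumour profile."""
        return self.spec.tumor.iso_radius_mm(ratio)

    def analytic_btv_cc(self, ratio: float) -> float:
        """Closed-form volume (cm³) of the true BTV ball at a T/N ratio."""
        r_cm = self.iso_radius_mm(ratio) / 10.0
        return 4.0 / 3.0 * np.pi * r_cm ** 3

    def true_btv_mask(self, ratio: float) -> StructureMask:
        """Voxelised ground-truth BTV: profile >= ratio × background, inside
        the brain, excluding the basal ganglia.

        Uses the same arithmetic as the noiseless image construction, so on
        a noiseless, unsmoothed phantom the thresholding pipeline recovers
        this mask exactly.
        """
        tn = _tumor_tn_field(self.spec, self.grid)
        brain = _brain_mask(self.spec, self.grid)
        _, bg_union = _basal_ganglia_fields(self.spec, self.grid)
        cutoff = float(ratio) * float(self.spec.background_suv)
        data = (self.spec.background_suv * tn >= cutoff) & brain & ~bg_union
        return StructureMask(data, self.grid, Role.BTV, f"trueBTV{ratio:g}")


@dataclass
class PhantomResult:
    """Generated digital patient: SUV image, structure masks, dose, truth."""

    suv: ImageVolume
    masks: dict[Role, StructureMask]
    dose: ImageVolume
    truth: GroundTruth


def make_recurrence(reference: StructureMask, center_offset_mm, radius_mm: float,
                    designed_outside_fraction: float) -> tuple[StructureMask, float]:
    """A recurrence blob with an exact designed fraction outside a reference.

    The blob is anchored at the reference surface voxel nearest the requested
    centre and assembled voxel-by-voxel: with N the voxel count of a
    ``radius_mm`` ball, it takes the round(f·N) outside voxels and the
    remaining inside voxels nearest the anchor, so the achieved fraction is
    within half a voxel of the design. Returns (mask, achieved_fraction).
    """
    if not (0.0 <= designed_outside_fraction <= 1.0):
        raise ValueError("designed fraction must lie in [0, 1]")
    if reference.is_empty():
        raise ValueError("reference mask is empty")
    grid = reference.grid
    center = _abs_center(grid, center_offset_mm)

    # anchor: reference surface voxel nearest the requested centre
    interior = ndimage.binary_erosion(reference.data, border_value=0)
    surf_idx = np.argwhere(reference.data & ~interior)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    surf_mm = surf_idx * spacing + origin
    anchor = surf_mm[np.argmin(((surf_mm - np.asarray(center)) ** 2).sum(axis=1))]

    d = _radius_field(grid, tuple(anchor))
    n_total = int(np.count_nonzero(d <= radius_mm))
    if n_total == 0:
        raise ValueError("recurrence radius too small for this grid")
    k_out = int(round(designed_outside_fraction * n_total))

    flat_d = d.ravel()
    flat_ref = reference.data.ravel()
    order = np.argsort(flat_d, kind="stable")
    inside_sorted = order[flat_ref[order]]
    outside_sorted = order[~flat_ref[order]]
    if len(outside_sorted) < k_out or len(inside_sorted) < n_total - k_out:
        raise ValueError(
            f"infeasible designed fraction {designed_outside_fraction} for this geometry"
        )
    chosen = np.concatenate([outside_sorted[:k_out], inside_sorted[: n_total - k_out]])
    data = np.zeros(grid.shape, dtype=bool)
    data.ravel()[chosen] = True
    achieved = k_out / n_total
    return StructureMask(data, grid, Role.RECURRENCE, "recurrence"), achieved


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the digital patient described by a :class:`PhantomSpec`.

    Deterministic given ``spec.seed``; changing only the seed changes only
    the noise realisation, never the masks. Raises if the tumour's
    infiltration ball extends outside the brain.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    brain = _brain_mask(spec, grid)
    tumor_center = _abs_center(grid, spec.tumor.center_offset_mm)
    r_tumor = _radius_field(grid, tumor_center)
    if np.any((r_tumor <= spec.tumor.infiltration_radius_mm) & ~brain):
        raise ValueError("tumour infiltration region extends outside the brain")

    tn_tumor = spec.tumor.tn_at_radius(r_tumor)
    tn_bg, bg_union = _basal_ganglia_fields(spec, grid)
    suv_data = spec.background_suv * np.maximum(tn_tumor, tn_bg)
    suv_data = np.where(brain, suv_data, 0.0)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm / 2.354820045 / s for s in spec.spacing]
        suv_data = ndimage.gaussian_filter(suv_data, sigma=sigma_vox)
    if spec.noise_sigma_fraction > 0:
        suv_data = suv_data * (1.0 + spec.noise_sigma_fraction * rng.standard_normal(grid.shape))
        suv_data = np.clip(suv_data, 0.0, None)

    suv = ImageVolume(suv_data, grid, Unit.SUV)

    brain_mask = StructureMask(brain, grid, Role.BRAIN, "brain")
    gtv = StructureMask((r_tumor <= spec.tumor.enhancement_radius_mm) & brain,
                        grid, Role.GTV, "GTV")
    bg_mask = StructureMask(bg_union, grid, Role.BASAL_GANGLIA, "basal ganglia")
    barrier = StructureMask(_barrier_mask(spec, grid), grid, Role.BARRIER, "barrier")

    policy = MarginPolicy(
        ctv_margin_mm=spec.ctv_margin_mm,
        ptv_margin_mm=spec.ptv_margin_mm,
        barriers=(barrier,) if not barrier.is_empty() else (),
        bound=brain_mask,
    )
    ctv, ptv = build_targets(gtv, policy)

    dist_out = ndimage.distance_transform_edt(~ptv.data, sampling=spec.spacing)
    falloff = np.clip(1.0 - dist_out / spec.dose_falloff_mm, 0.0, 1.0) if spec.dose_falloff_mm > 0 \
        else (dist_out == 0).astype(float)
    dose = ImageVolume(spec.prescription_Gy * falloff, grid, Unit.GY)

    masks = {Role.BRAIN: brain_mask, Role.GTV: gtv, Role.BASAL_GANGLIA: bg_mask,
             Role.CTV: ctv, Role.PTV: ptv}
    if not barrier.is_empty():
        masks[Role.BARRIER] = barrier

    truth = GroundTruth(spec=spec, grid=grid,
                        brain_cc=volume_cc(brain_mask), gtv_cc=volume_cc(gtv))

    if spec.recurrence is not None:
        ref = masks[spec.recurrence.vs_role]
        rec, achieved = make_recurrence(ref, spec.recurrence.center_offset_mm,
                                        spec.recurrence.radius_mm,
                                        spec.recurrence.designed_outside_fraction)
        masks[Role.RECURRENCE] = rec
        truth.recurrence_outside_fraction = achieved

    return PhantomResult(suv=suv, masks=masks, dose=dose, truth=truth)


def save_phantom(result: PhantomResult, outdir, case_id: str = "phantom") -> Path:
    """Write SUV, dose, masks (``<case>_<ROLE>.nii.gz``) and truth.json."""
    from . import io as _io  # deferred: keeps phantom importable without nibabel at doc time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_volume(result.suv, outdir / f"{case_id}_SUV.nii.gz")
    _io.write_volume(result.dose, outdir / f"{case_id}_DOSE.nii.gz")
    for role, mask in result.masks.items():
        _io.write_mask(mask, outdir / f"{case_id}_{role.value}.nii.gz")
    truth = {
        "spec": result.truth.spec.to_dict(),
        "brain_cc": result.truth.brain_cc,
        "gtv_cc": result.truth.gtv_cc,
        "recurrence_outside_fraction": result.truth.recurrence_outside_fraction,
    }
    with open(outdir / f"{case_id}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return outdir
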