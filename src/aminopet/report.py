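"""Per-case pipeline orchestration and cohort aggregation.

`analyze_case` composes the module chain — normal-reference ROI → T/N
thresholding → concordance vs GTV → dose coverage → recurrence overlap —
into one `CaseResult`; `summarize_cohort` aggregates a list of cases into
mean/min/max summaries, mirroring how such cohorts are reported (per-case
table rows with total / within-GTV / outside-GTV volumes per threshold,
plus cohort mean and range).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .grids import ImageVolume, Role, StructureMask, volume_cc
from .metrics import ConcordanceReport, concordance, dose_coverage, recurrence_analysis
from .segmentation import TnThreshold, keep_components, segment_btv
from .suv import place_sphere_roi, roi_stats

__all__ = [
    "ThresholdMetrics",
    "CaseResult",
    "analyze_case",
    "run_phantom_case",
    "run_case",
    "results_to_frame",
    "summarize_cohort",
    "write_outputs",
]

DEFAULT_RATIOS = (1.7, 2.0)


@dataclass(frozen=True)
class ThresholdMetrics:
    """All per-threshold quantities of one case."""

    ratio: float
    btv_cc: float
    within_cc: float
    outside_cc: float
    outside_fraction: float
    hd95_mm: float
    svc_max_mm: float
    svc_mean_mm: float
    covered_fraction: Optional[float] = None


@dataclass
class CaseResult:
    """One case's GTV volume, per-threshold metrics, and recurrence overlap."""

    case_id: str
    gtv_cc: float
    normal_reference: float
    thresholds: dict[float, ThresholdMetrics] = field(default_factory=dict)
    recurrence_outside: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {"case_id": self.case_id, "gtv_cc": self.gtv_cc,
                     "normal_reference": self.normal_reference}
        for ratio, tm in sorted(self.thresholds.items()):
            tag = f"btv{ratio:g}"
            row[f"{tag}_cc"] = tm.btv_cc
            row[f"{tag}_within_cc"] = tm.within_cc
            row[f"{tag}_outside_cc"] = tm.outside_cc
            row[f"{tag}_outside_fraction"] = tm.outside_fraction
            row[f"{tag}_hd95_mm"] = tm.hd95_mm
            row[f"{tag}_svc_max_mm"] = tm.svc_max_mm
            row[f"{tag}_svc_mean_mm"] = tm.svc_mean_mm
            if tm.covered_fraction is not None:
                row[f"{tag}_covered_fraction"] = tm.covered_fraction
        for name, frac in sorted(self.recurrence_outside.items()):
            row[f"recurrence_outside_{name}"] = frac
        return row


def analyze_case(case_id: str,
                 suv: ImageVolume,
                 gtv: StructureMask,
                 brain: StructureMask,
                 normal_reference: float,
                 exclusions: Sequence[StructureMask] = (),
                 ratios: Sequence[float] = DEFAULT_RATIOS,
                 dose: ImageVolume | None = None,
                 prescription_Gy: float | None = None,
                 iso_fraction: float = 0.95,
                 recurrence: StructureMask | None = None,
                 recurrence_references: Mapping[str, StructureMask] | None = None,
                 component_policy: str = "all") -> CaseResult:
    """Run the full per-case analysis on in-memory volumes.

    Deterministic given its inputs. Per T/N ratio: segment the BTV, compute
    the within/outside decomposition and surface distances vs the GTV, and
    (when a dose grid is supplied) the isodose coverage fraction. When a
    recurrence mask is present, its outside-fraction is computed against the
    GTV, every BTV, and any additional reference structures supplied.
    """
    result = CaseResult(case_id=case_id, gtv_cc=volume_cc(gtv),
                        normal_reference=float(normal_reference))
    btvs: dict[str, StructureMask] = {}
    for ratio in ratios:
        thr = TnThreshold(ratio=float(ratio), normal_reference=float(normal_reference))
        btv = segment_btv(suv, thr, brain, exclusions)
        if component_policy != "all":
            btv = keep_components(btv, component_policy)
        rep: ConcordanceReport = concordance(gtv, btv)
        covered = None
        if dose is not None:
            if prescription_Gy is None:
                raise ValueError("dose supplied without a prescription")
            covered = dose_coverage(dose, btv, prescription_Gy, iso_fraction).covered_fraction
        result.thresholds[float(ratio)] = ThresholdMetrics(
            ratio=float(ratio), btv_cc=rep.total_cc, within_cc=rep.within_cc,
            outside_cc=rep.outside_cc, outside_fraction=rep.outside_fraction,
            hd95_mm=rep.hd95_mm, svc_max_mm=rep.svc_max_mm, svc_mean_mm=rep.svc_mean_mm,
            covered_fraction=covered)
        btvs[f"BTV{ratio:g}"] = btv

    if recurrence is not None:
        refs: dict[str, StructureMask] = {"GTV": gtv, **btvs}
        if recurrence_references:
            refs.update(recurrence_references)
        result.recurrence_outside = recurrence_analysis(recurrence, refs)
    return result


def run_phantom_case(case_id, spec, ratios: Sequence[float] = DEFAULT_RATIOS,
                     normal_stat: str = "mean"):
    """Generate a phantom and analyse it exactly as a patient case.

    The contralateral normal reference is measured with a 10 mm sphere ROI
    at the mirror position of the tumour centre (x negated), emulating the
    centrum-semiovale reference of the clinical procedure. Returns
    (CaseResult, PhantomResult).
    """
    from .phantom import generate_phantom, _abs_center  # local import avoids cycle

    result = generate_phantom(spec)
    grid = result.suv.grid
    off = spec.tumor.center_offset_mm
    mirror = _abs_center(grid, (-off[0], off[1], off[2]))
    roi = place_sphere_roi(grid, mirror, diameter_mm=10.0, label="contralateral WM")
    stats = roi_stats(result.suv, roi)
    normal_ref = stats.mean if normal_stat == "mean" else stats.max

    rec = result.masks.get(Role.RECURRENCE)
    extra_refs = {"PTV": result.masks[Role.PTV]} if rec is not None else None
    case = analyze_case(
        case_id=case_id,
        suv=result.suv,
        gtv=result.masks[Role.GTV],
        brain=result.masks[Role.BRAIN],
        normal_reference=normal_ref,
        exclusions=[result.masks[Role.BASAL_GANGLIA]],
        ratios=ratios,
        dose=result.dose,
        prescription_Gy=spec.prescription_Gy,
        recurrence=rec,
        recurrence_references=extra_refs,
    )
    return case, result


def run_case(manifest: Mapping, base_dir=".") -> CaseResult:
    """Run one case from a file manifest (paths relative to ``base_dir``).

    Required keys: ``case_id``, ``suv``, ``gtv``, ``brain`` and either
    ``normal_ref`` (an SUV value) or ``normal_roi_center_mm`` (a 10 mm
    sphere ROI is placed there). Optional: ``exclusions`` (list of mask
    paths), ``thresholds``, ``dose`` + ``prescription_gy`` (+
    ``iso_fraction``), ``recurrence``, ``references`` (name → mask path),
    ``roi_diameter_mm``, ``normal_stat``.
    """
    base = Path(base_dir)

    def p(rel):
        return base / rel

    case_id = str(manifest["case_id"])
    suv = _io.read_volume(p(manifest["suv"]))
    gtv = _io.read_mask(p(manifest["gtv"]), role=Role.GTV)
    brain = _io.read_mask(p(manifest["brain"]), role=Role.BRAIN)
    exclusions = [_io.read_mask(p(m)) for m in manifest.get("exclusions", [])]

    if "normal_ref" in manifest:
        normal_ref = float(manifest["normal_ref"])
    elif "normal_roi_center_mm" in manifest:
        roi = place_sphere_roi(suv.grid, manifest["normal_roi_center_mm"],
                               diameter_mm=float(manifest.get("roi_diameter_mm", 10.0)))
        stats = roi_stats(suv, roi)
        normal_ref = stats.mean if manifest.get("normal_stat", "mean") == "mean" else stats.max
    else:
        raise ValueError(f"{case_id}: manifest needs 'normal_ref' or 'normal_roi_center_mm'")

    dose = _io.read_volume(p(manifest["dose"])) if "dose" in manifest else None
    rec = _io.read_mask(p(manifest["recurrence"]), role=Role.RECURRENCE) \
        if "recurrence" in manifest else None
    refs = {name: _io.read_mask(p(path)) for name, path in manifest.get("references", {}).items()}

    try:
        return analyze_case(
            case_id=case_id, suv=suv, gtv=gtv, brain=brain,
            normal_reference=normal_ref, exclusions=exclusions,
            ratios=[float(r) for r in manifest.get("thresholds", DEFAULT_RATIOS)],
            dose=dose, prescription_Gy=manifest.get("prescription_gy"),
            iso_fraction=float(manifest.get("iso_fraction", 0.95)),
            recurrence=rec, recurrence_references=refs or None,
            component_policy=manifest.get("component_policy", "all"))
    except Exception as exc:
        raise RuntimeError(f"case {case_id}: {exc}") from exc


def results_to_frame(results: Sequence[CaseResult]) -> pd.DataFrame:
    """One row per case, one column per metric."""
    if not results:
        raise ValueError("no case results")
    return pd.DataFrame([r.to_row() for r in results])


def summarize_cohort(results: Sequence[CaseResult]) -> dict[str, dict]:
    """Mean/min/max/n for every numeric metric over the cohort.

    Cases missing a metric (e.g. no recurrence) simply do not contribute to
    that metric's n. Permutation-invariant in case order.
    """
    frame = results_to_frame(results)
    out: dict[str, dict] = {}
    for col in frame.columns:
        if col == "case_id":
            continue
        vals = pd.to_numeric(frame[col], errors="coerce").dropna()
        if vals.empty:
            continue
        out[col] = {"mean": float(vals.mean()), "min": float(vals.min()),
                    "max": float(vals.max()), "n": int(vals.size)}
    return out


def write_outputs(results: Sequence[CaseResult], outdir) -> tuple[Path, Path]:
    """Per-case CSV plus JSON cohort summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "cases.csv"
    results_to_frame(results).to_csv(csv_path, index=False)
    summary_path = outdir / "cohort_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summarize_cohort(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, summary_path
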