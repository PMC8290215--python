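"""Biological target volume delineation by tumour-to-normal SUV thresholding.

A voxel belongs to the BTV when its SUV is at least ``ratio × normal_reference``
(inclusive), where the normal reference is measured in contralateral white
matter. Ratios 1.7 and 2.0 are the guideline thresholds for amino-acid PET in
high-grade glioma. Physiologically avid structures (basal ganglia for FDOPA)
are removed with caller-supplied exclusion masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .grids import ImageVolume, Role, StructureMask, Unit, require_coregistered

__all__ = ["TnThreshold", "segment_btv", "keep_components"]


@dataclass(frozen=True)
class TnThreshold:
    """A tumour-to-normal ratio threshold anchored to a normal-tissue SUV."""

    ratio: float
    normal_reference: float

    def __post_init__(self) -> None:
        if not (self.ratio > 0):
            raise ValueError(f"T/N ratio must be positive, got {self.ratio}")
        if not (self.normal_reference > 0):
            raise ValueError(f"normal reference SUV must be positive, got {self.normal_reference}")

    @property
    def suv_cutoff(self) -> float:
        return self.ratio * self.normal_reference


def segment_btv(suv: ImageVolume, thr: TnThreshold, brain: StructureMask,
                exclusions: Sequence[StructureMask] = ()) -> StructureMask:
    """Threshold the SUV image inside the brain and drop excluded regions.

    BTV = { v in brain : SUV(v) >= ratio × normal_reference } minus the union
    of the exclusion masks. The comparison is inclusive, so multiplying the
    image and the reference by the same constant leaves the result unchanged.
    """
    suv.require_unit(Unit.SUV, "segment_btv")
    require_coregistered(suv, brain, *exclusions)
    if brain.is_empty():
        raise ValueError("brain mask is empty")
    out = (suv.data >= thr.suv_cutoff) & brain.data
    for exc in exclusions:
        out &= ~exc.data
    return StructureMask(out, suv.grid, Role.BTV, f"BTV{thr.ratio:g}")


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def keep_components(mask: StructureMask,
                    policy: Literal["all", "largest", "touching_seed"] = "all",
                    seed_mm=None) -> StructureMask:
    """Filter 26-connected components of a mask.

    ``all`` is the identity; ``largest`` keeps the biggest component (ties
    broken by lowest label index, i.e. scan order); ``touching_seed`` keeps
    the component containing the voxel nearest ``seed_mm`` and errors if that
    voxel is outside every component.
    """
    if policy == "all":
        return mask.with_data(mask.data)
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n == 0:
        if policy == "largest":
            return mask.with_data(mask.data)
        raise ValueError("mask has no components to match the seed")
    if policy == "largest":
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        return mask.with_data(labels == int(np.argmax(counts)))
    if policy == "touching_seed":
        if seed_mm is None:
            raise ValueError("policy 'touching_seed' requires seed_mm")
        idx = mask.grid.index_of_mm(seed_mm)
        lab = int(labels[idx])
        if lab == 0:
            raise ValueError(f"seed point {tuple(seed_mm)} lies outside every component")
        return mask.with_data(labels == lab)
    raise ValueError(f"unknown component policy {policy!r}")
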