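"""CTV/PTV construction by physical-distance margin expansion.

Following the EORTC convention for glioblastoma, the clinical target volume
is the gross tumour volume expanded by 2 cm for microscopic spread, clipped
at anatomical barriers, and the planning target volume adds a 3–5 mm setup
margin. Expansion is based on the Euclidean distance transform with the
voxel spacing as sampling, so it is correct on anisotropic grids (unlike
structuring-element dilation). Barrier voxels are removed from the expanded
set but do not shadow regions behind them; reachability is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grids import Role, StructureMask, require_coregistered

__all__ = ["MarginPolicy", "expand_margin", "build_targets"]


@dataclass(frozen=True)
class MarginPolicy:
    """Margins (mm) and anatomical constraints for target construction."""

    ctv_margin_mm: float = 20.0
    ptv_margin_mm: float = 3.0
    barriers: tuple[StructureMask, ...] = ()
    bound: StructureMask | None = None

    def __post_init__(self) -> None:
        if self.ctv_margin_mm < 0 or self.ptv_margin_mm < 0:
            raise ValueError("margins must be non-negative")
        object.__setattr__(self, "barriers", tuple(self.barriers))


def expand_margin(mask: StructureMask, margin_mm: float,
                  barriers: Sequence[StructureMask] = (),
                  bound: StructureMask | None = None,
                  role: Role = Role.OTHER) -> StructureMask:
    """All voxels within ``margin_mm`` (mm, Euclidean) of the mask.

    The result is clipped to ``bound`` (full grid if None) and barrier
    voxels are removed. A zero margin returns the mask itself after
    clipping. Distances are measured between voxel centres with the grid's
    physical spacing.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    extra = list(barriers) + ([bound] if bound is not None else [])
    require_coregistered(mask, *extra)
    if mask.is_empty():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        out = mask.data.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.grid.spacing)
        out = dist <= margin_mm
    if bound is not None:
        out &= bound.data
    for b in barriers:
        out &= ~b.data
    return StructureMask(out, mask.grid, role, mask.label)


def build_targets(gtv: StructureMask, policy: MarginPolicy) -> tuple[StructureMask, StructureMask]:
    """CTV and PTV from a GTV under a margin policy.

    CTV expands the GTV by the CTV margin; the PTV adds the setup margin to
    the CTV. Both stay inside the bound and never include barrier voxels,
    so GTV∩bound∖barriers ⊆ CTV ⊆ PTV.
    """
    if gtv.is_empty():
        raise ValueError("GTV is empty")
    ctv = expand_margin(gtv, policy.ctv_margin_mm, policy.barriers, policy.bound, role=Role.CTV)
    if ctv.is_empty():
        raise ValueError("CTV is empty after barrier/bound clipping")
    ptv = expand_margin(ctv, policy.ptv_margin_mm, policy.barriers, policy.bound, role=Role.PTV)
    ctv.label, ptv.label = "CTV", "PTV"
    return ctv, ptv
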