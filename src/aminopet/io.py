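"""NIfTI reading/writing for volumes and masks, plus JSON sidecar metadata.

Volumes are stored as .nii/.nii.gz with a diagonal affine (spacing on the
diagonal, origin in the translation column). The unit tag and optional
acquisition metadata travel in a JSON sidecar next to the image
(``case.nii.gz`` → ``case.json``). Mask role can come from the sidecar, an
explicit argument, or the ``<case>_<ROLE>.nii.gz`` filename convention.
Rotated/oblique affines are rejected: the pipeline assumes axis-aligned,
co-registered grids and never resamples.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import Grid, ImageVolume, Role, StructureMask, Unit, volume_cc

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "sidecar_path",
    "read_sidecar",
    "write_sidecar",
]

_NII_SUFFIX = re.compile(r"\.nii(\.gz)?$", re.IGNORECASE)


def sidecar_path(path) -> Path:
    """JSON sidecar path for a NIfTI file (strip .nii/.nii.gz, add .json)."""
    p = Path(path)
    stem = _NII_SUFFIX.sub("", p.name)
    return p.with_name(stem + ".json")


def read_sidecar(path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        return {}
    with open(sp) as fh:
        return json.load(fh)


def write_sidecar(path, meta: dict) -> Path:
    sp = sidecar_path(path)
    with open(sp, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sp


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_nifti(img) -> Grid:
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("oblique/rotated NIfTI affines are not supported; grids must be axis-aligned")
    spacing = tuple(float(abs(d)) for d in np.diag(rot))
    origin = tuple(float(v) for v in aff[:3, 3])
    return Grid(tuple(int(s) for s in img.shape[:3]), spacing, origin)


def _load(path):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image: {p}")
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{p}: expected a 3-D payload, got shape {data.shape}")
    return img, data


def read_volume(path, unit: Unit | str | None = None) -> ImageVolume:
    """Read a scalar volume; the unit comes from the sidecar unless given.

    Raises if the file is missing, the payload is not 3-D, voxels are
    non-finite, or no unit can be determined.
    """
    img, data = _load(path)
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite voxel values")
    if unit is None:
        unit = read_sidecar(path).get("unit")
    if unit is None:
        raise ValueError(
            f"{path}: no unit tag; supply unit= or provide a JSON sidecar with a 'unit' field"
        )
    return ImageVolume(data, _grid_from_nifti(img), Unit(unit))


def write_volume(vol: ImageVolume, path, extra_meta: dict | None = None) -> Path:
    """Write a volume as NIfTI plus a JSON sidecar carrying the unit tag."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), _affine(vol.grid)), str(p))
    meta = {"unit": vol.unit.value}
    if extra_meta:
        meta.update(extra_meta)
    write_sidecar(p, meta)
    return p


def _role_from_name(path) -> Role | None:
    stem = _NII_SUFFIX.sub("", Path(path).name)
    tail = stem.rsplit("_", 1)[-1].upper()
    try:
        return Role(tail)
    except ValueError:
        return None


def read_mask(path, role: Role | str | None = None) -> StructureMask:
    """Read a binary mask; role from argument, sidecar, or filename suffix."""
    img, data = _load(path)
    mask = np.asarray(data) != 0
    if role is None:
        role = read_sidecar(path).get("role")
    if role is None:
        role = _role_from_name(path)
    label = read_sidecar(path).get("label", "")
    return StructureMask(mask, _grid_from_nifti(img), Role(role) if role else Role.OTHER, label)


def write_mask(mask: StructureMask, path, extra_meta: dict | None = None) -> Path:
    """Write a mask as a {0,1} NIfTI plus sidecar with role and volume."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.grid)), str(p))
    meta = {"role": mask.role.value, "label": mask.label, "volume_cc": volume_cc(mask)}
    if extra_meta:
        meta.update(extra_meta)
    write_sidecar(p, meta)
    return p
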