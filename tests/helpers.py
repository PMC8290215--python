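"""Brute-force oracles and random-mask generators for the test suite.

Everything here is deliberately naive (explicit loops / full pairwise
distance matrices) and independent of the library's implementation paths,
so it can serve as an exhaustive reference on small inputs.
"""

from __future__ import annotations

import numpy as np

from aminopet import Grid, StructureMask


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw) -> StructureMask:
    return StructureMask.from_array(np.asarray(data, dtype=bool), spacing, origin, **kw)


def random_blob(rng: np.random.Generator, shape=(14, 16, 12), spacing=(1.0, 1.0, 1.0),
                threshold_pct=75.0) -> StructureMask:
    """A random connected-ish blob from thresholded smoothed noise; never empty."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
        mask = field >= np.percentile(field, threshold_pct)
        if mask.any():
            return make_mask(mask, spacing)


def brute_surface(data: np.ndarray) -> np.ndarray:
    """Surface voxels by explicit 6-neighbour check (grid edge = outside)."""
    padded = np.pad(np.asarray(data, dtype=bool), 1, constant_values=False)
    out = np.zeros_like(np.asarray(data, dtype=bool))
    for i, j, k in np.argwhere(data):
        pi, pj, pk = i + 1, j + 1, k + 1
        neighbours = [padded[pi - 1, pj, pk], padded[pi + 1, pj, pk],
                      padded[pi, pj - 1, pk], padded[pi, pj + 1, pk],
                      padded[pi, pj, pk - 1], padded[pi, pj, pk + 1]]
        if not all(neighbours):
            out[i, j, k] = True
    return out


def _surface_points_mm(mask: StructureMask) -> np.ndarray:
    idx = np.argwhere(brute_surface(mask.data)).astype(float)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def brute_hd95(source: StructureMask, target: StructureMask, percentile=95.0) -> float:
    """Directed percentile Hausdorff distance by full pairwise distances."""
    src = _surface_points_mm(source)
    tgt = _surface_points_mm(target)
    dmat = np.sqrt(((src[:, None, :] - tgt[None, :, :]) ** 2).sum(axis=2))
    return float(np.percentile(dmat.min(axis=1), percentile))


def brute_svc(gtv: StructureMask, btv: StructureMask) -> tuple[float, float]:
    """SVC max/mean distance by per-voxel loop over BTV∖GTV."""
    svc_idx = np.argwhere(btv.data & ~gtv.data).astype(float)
    if svc_idx.size == 0:
        return 0.0, 0.0
    pts = svc_idx * np.asarray(btv.spacing) + np.asarray(btv.origin)
    tgt = _surface_points_mm(gtv)
    dmat = np.sqrt(((pts[:, None, :] - tgt[None, :, :]) ** 2).sum(axis=2))
    dmin = dmat.min(axis=1)
    return float(dmin.max()), float(dmin.mean())


def brute_sphere_count(grid: Grid, center_mm, radius_mm) -> int:
    """Number of voxel centres within radius of a point, by triple loop."""
    count = 0
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = (grid.origin[0] + i * grid.spacing[0],
                     grid.origin[1] + j * grid.spacing[1],
                     grid.origin[2] + k * grid.spacing[2])
                d2 = sum((p[a] - center_mm[a]) ** 2 for a in range(3))
                if d2 <= radius_mm ** 2:
                    count += 1
    return count


def brute_flood_fill_labels(data: np.ndarray) -> list[set]:
    """26-connected components by breadth-first flood fill; list of voxel sets."""
    data = np.asarray(data, dtype=bool)
    seen = np.zeros_like(data)
    comps = []
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(data)):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[a] < data.shape[a] for a in range(3)) and data[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps
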