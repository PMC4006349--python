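"""Segmentation agreement metrics: Dice overlap and zero-set Hausdorff."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .grid import LevelSetField
from .levelset import interface_points

__all__ = ["dice", "hausdorff_zero_sets", "boundary_cell_count", "boundary_cells"]


def dice(a: LevelSetField | np.ndarray, b: LevelSetField | np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of the interior (phi > 0) masks."""
    ma = a.interior_mask() if isinstance(a, LevelSetField) else np.asarray(a, bool)
    mb = b.interior_mask() if isinstance(b, LevelSetField) else np.asarray(b, bool)
    inter = np.logical_and(ma, mb).sum()
    total = ma.sum() + mb.sum()
    if total == 0:
        return 1.0
    return 2.0 * float(inter) / float(total)


def hausdorff_zero_sets(a: LevelSetField, b: LevelSetField) -> float:
    """Symmetric Hausdorff distance between the two zero level sets.

    Both interfaces are sampled at sub-cell resolution; the distance is in
    physical units.
    """
    pa = interface_points(a)
    pb = interface_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("a field has no interface; Hausdorff undefined")
    d_ab = cKDTree(pb).query(pa, workers=1)[0].max()
    d_ba = cKDTree(pa).query(pb, workers=1)[0].max()
    return float(max(d_ab, d_ba))


def boundary_cells(phi: LevelSetField) -> np.ndarray:
    """Boolean mask of interior cells with at least one exterior neighbor."""
    inside = phi.interior_mask()
    boundary = np.zeros_like(inside)
    for axis in range(inside.ndim):
        for shift in (1, -1):
            neighbor = np.roll(inside, shift, axis=axis)
            edge = [slice(None)] * inside.ndim
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            neighbor[tuple(edge)] = inside[tuple(edge)]
            boundary |= inside & ~neighbor
    return boundary


def boundary_cell_count(phi: LevelSetField) -> int:
    """Number of boundary cells of the interior region (manual-tracing cost)."""
    return int(boundary_cells(phi).sum())
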