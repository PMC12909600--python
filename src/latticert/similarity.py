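"""Contour-similarity metrics: Dice coefficient and mean surface distance."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import StructureMask

__all__ = ["dice", "mean_surface_distance", "boundary_voxels"]


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Both masks must share a grid. Two empty masks are identical by
    convention and score 1.0.
    """
    a.grid.require_same(b.grid, "dice")
    na = int(a.occupancy.sum())
    nb = int(b.occupancy.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.occupancy & b.occupancy).sum())
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: StructureMask) -> np.ndarray:
    """World coordinates (mm) of boundary voxel centers.

    A boundary voxel is occupied but 6-face-adjacent to at least one
    unoccupied voxel (voxels on the grid edge count as boundary).
    """
    occ = mask.occupancy
    interior = ndimage.binary_erosion(occ)  # border_value=0: grid edge is exterior
    idx = np.argwhere(occ & ~interior)
    return mask.grid.index_to_world(idx)


def mean_surface_distance(a: StructureMask, b: StructureMask) -> float:
    """Symmetric mean surface distance in mm between two masks' boundaries.

    Average of the two directed mean nearest-neighbour distances between
    the boundary voxel-center sets. Raises on empty masks.
    """
    a.grid.require_same(b.grid, "mean_surface_distance")
    if a.is_empty or b.is_empty:
        raise ValueError("mean_surface_distance requires non-empty masks")
    pa = boundary_voxels(a)
    pb = boundary_voxels(b)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
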