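"""Independent brute-force oracles for small-grid cross-checks.

These deliberately avoid the implementation's code paths (no EDT, no KD
trees, no early termination): everything is exhaustive enumeration over
voxel centers, affordable only on tiny grids.
"""

import numpy as np
from scipy.spatial.distance import cdist


def mask_points(mask):
    """World coordinates of all occupied voxel centers."""
    return mask.grid.index_to_world(np.argwhere(mask.occupancy).astype(float))


def brute_expand(mask, margin_mm):
    """Exhaustive expansion: distance from every voxel center to every
    occupied center."""
    grid = mask.grid
    all_idx = np.argwhere(np.ones(grid.dims, dtype=bool)).astype(float)
    all_pts = grid.index_to_world(all_idx)
    occ_pts = mask_points(mask)
    if occ_pts.size == 0:
        return np.zeros(grid.dims, dtype=bool)
    dmin = cdist(all_pts, occ_pts).min(axis=1)
    return (dmin <= margin_mm).reshape(grid.dims)


def brute_retract(mask, margin_mm):
    grid = mask.grid
    out_idx = np.argwhere(~mask.occupancy).astype(float)
    occ_idx = np.argwhere(mask.occupancy).astype(float)
    if out_idx.size == 0:
        return mask.occupancy.copy()
    if occ_idx.size == 0:
        return np.zeros(grid.dims, dtype=bool)
    dmin = cdist(grid.index_to_world(occ_idx), grid.index_to_world(out_idx)).min(axis=1)
    out = np.zeros(grid.dims, dtype=bool)
    keep = occ_idx[dmin > margin_mm].astype(int)
    out[keep[:, 0], keep[:, 1], keep[:, 2]] = True
    return out


def brute_boundary(mask):
    """Boundary voxel centers: occupied with a 6-neighbour unoccupied or on
    the grid edge."""
    occ = mask.occupancy
    pad = np.pad(occ, 1, constant_values=False)
    interior = np.ones_like(occ)
    for ax in range(3):
        for d in (-1, 1):
            interior &= np.roll(pad, d, axis=ax)[1:-1, 1:-1, 1:-1]
    return mask.grid.index_to_world(np.argwhere(occ & ~interior).astype(float))


def brute_msd(a, b):
    pa, pb = brute_boundary(a), brute_boundary(b)
    d = cdist(pa, pb)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_dose_at_volume(dose, mask, v_cc):
    """Sorted-cumulative D(v) with the same partial-voxel interpolation
    convention, recomputed from first principles."""
    vals = np.sort(dose.dose_gy[mask.occupancy])[::-1]
    vv = mask.grid.voxel_volume_cc
    if v_cc <= vv:
        return float(vals[0])
    k = int(np.floor(v_cc / vv))
    frac = v_cc / vv - k
    if k >= vals.size:
        return float(vals[-1])
    if frac == 0:
        return float(vals[k - 1])
    return float(vals[k - 1] + frac * (vals[k] - vals[k - 1]))


def brute_volume_at_dose_pct(dose, mask, threshold):
    vals = dose.dose_gy[mask.occupancy]
    return 100.0 * float((vals >= threshold).sum()) / vals.size


def brute_gamma(reference, evaluated, criteria, search_radius_factor=3.0):
    """Exhaustive gamma over evaluated voxel centers within the search
    radius (no interpolation, no early exit)."""
    ref_max = reference.dose_gy.max()
    thresh = criteria.low_dose_threshold_pct / 100.0 * ref_max
    delta = criteria.dose_diff_pct / 100.0 * ref_max
    radius = search_radius_factor * criteria.dta_mm

    ref_idx = np.argwhere(reference.dose_gy >= thresh)
    ref_pts = reference.grid.index_to_world(ref_idx.astype(float))
    ref_d = reference.dose_gy[tuple(ref_idx.T)]

    ev_idx = np.argwhere(np.ones(evaluated.grid.dims, dtype=bool))
    ev_pts = evaluated.grid.index_to_world(ev_idx.astype(float))
    ev_d = evaluated.dose_gy[tuple(ev_idx.T)]

    gammas = np.empty(ref_d.size)
    for i in range(ref_d.size):
        dr = np.linalg.norm(ev_pts - ref_pts[i], axis=1)
        near = dr <= radius
        g2 = (dr[near] / criteria.dta_mm) ** 2 + \
            ((ev_d[near] - ref_d[i]) / delta) ** 2
        gammas[i] = np.sqrt(g2.min()) if g2.size else np.inf
    pass_rate = 100.0 * float((gammas <= 1.0 + 1e-12).sum()) / gammas.size
    return gammas, pass_rate
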