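"""3D gamma-index comparison of two dose grids.

For every reference voxel above the low-dose threshold,

    gamma = min over evaluated positions r of
            sqrt( (|r - r_ref| / dta)^2 + ((D_eval(r) - D_ref) / delta)^2 )

with ``delta = dose_diff_pct % of the reference maximum`` (global
normalisation; local normalisation optional). The evaluated dose is
trilinearly interpolated during the search, which samples a cubic-grid
neighbourhood of step ``search_step_mm`` out to a radius of 3 x dta; a
voxel's search stops as soon as the remaining spatial term alone exceeds
its current best gamma, so the cap only affects voxels whose true optimum
lies beyond 3 x dta (where gamma > 3 regardless, far above the pass level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_3d", "CRITERIA_3_2", "CRITERIA_5_3"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma acceptance criteria: dose difference (% of reference max),
    distance-to-agreement (mm), and the low-dose cutoff (% of reference
    max) below which reference voxels are excluded from the pass rate."""

    dose_diff_pct: float = 5.0
    dta_mm: float = 3.0
    low_dose_threshold_pct: float = 10.0
    local_normalization: bool = False

    def __post_init__(self):
        if min(self.dose_diff_pct, self.dta_mm, self.low_dose_threshold_pct) <= 0:
            raise ValueError("gamma criteria must be positive")


#: Plan-acceptance preset (3 % / 2 mm, 10 % threshold).
CRITERIA_3_2 = GammaCriteria(3.0, 2.0, 10.0)
#: Secondary-verification preset (5 % / 3 mm, 10 % threshold).
CRITERIA_5_3 = GammaCriteria(5.0, 3.0, 10.0)


@dataclass
class GammaResult:
    gamma: np.ndarray = field(repr=False)  # NaN below threshold
    pass_rate_pct: float = 0.0
    n_evaluated: int = 0

    def __post_init__(self):
        self.pass_rate_pct = float(self.pass_rate_pct)


def gamma_3d(reference: DoseGrid, evaluated: DoseGrid,
             criteria: GammaCriteria = CRITERIA_5_3,
             search_step_mm: float | None = None,
             search_radius_factor: float = 3.0) -> GammaResult:
    """Compute the 3D gamma index of ``evaluated`` against ``reference``.

    The two grids need not be identical but must overlap; the evaluated
    dose is interpolated at search positions around each reference voxel
    center. ``search_step_mm`` defaults to half the smallest reference
    spacing.
    """
    ref_max = reference.max_gy
    if ref_max <= 0:
        raise ValueError("reference dose is identically zero")
    _require_overlap(reference, evaluated)

    step = search_step_mm or min(reference.grid.spacing_mm) / 2.0
    radius = search_radius_factor * criteria.dta_mm
    offsets = _search_offsets(step, radius)  # sorted by |offset|
    off_norm2 = (np.linalg.norm(offsets, axis=1) / criteria.dta_mm) ** 2

    thresh = criteria.low_dose_threshold_pct / 100.0 * ref_max
    sel = reference.dose_gy >= thresh
    ref_points = reference.grid.index_to_world(np.argwhere(sel).astype(float))
    ref_doses = reference.dose_gy[sel]

    if criteria.local_normalization:
        delta = criteria.dose_diff_pct / 100.0 * ref_doses
    else:
        delta = np.full(ref_doses.shape, criteria.dose_diff_pct / 100.0 * ref_max)

    gamma2 = np.full(ref_doses.shape, np.inf)
    active = np.arange(ref_doses.size)
    eval_origin = np.asarray(evaluated.grid.origin_mm)
    eval_spacing = np.asarray(evaluated.grid.spacing_mm)

    for i, off in enumerate(offsets):
        if active.size == 0:
            break
        pts = (ref_points[active] + off - eval_origin) / eval_spacing
        dvals = map_coordinates(evaluated.dose_gy, pts.T, order=1, mode="nearest")
        cand = off_norm2[i] + ((dvals - ref_doses[active]) / delta[active]) ** 2
        gamma2[active] = np.minimum(gamma2[active], cand)
        # a voxel is final once no farther offset can beat its current best
        next_spatial = off_norm2[i + 1] if i + 1 < len(offsets) else np.inf
        active = active[gamma2[active] > next_spatial]

    gamma_sel = np.sqrt(gamma2)
    gamma_full = np.full(reference.grid.dims, np.nan)
    gamma_full[sel] = gamma_sel
    n_eval = int(gamma_sel.size)
    pass_rate = 100.0 * float((gamma_sel <= 1.0 + 1e-12).sum()) / n_eval
    return GammaResult(gamma=gamma_full, pass_rate_pct=pass_rate, n_evaluated=n_eval)


def _search_offsets(step: float, radius: float) -> np.ndarray:
    k = int(np.floor(radius / step))
    ax = step * np.arange(-k, k + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    norms = np.linalg.norm(offs, axis=1)
    offs = offs[norms <= radius + 1e-9]
    order = np.argsort(np.linalg.norm(offs, axis=1), kind="stable")
    return offs[order]


def _require_overlap(reference: DoseGrid, evaluated: DoseGrid) -> None:
    for ax in range(3):
        r_lo = reference.grid.origin_mm[ax]
        r_hi = r_lo + (reference.grid.dims[ax] - 1) * reference.grid.spacing_mm[ax]
        e_lo = evaluated.grid.origin_mm[ax]
        e_hi = e_lo + (evaluated.grid.dims[ax] - 1) * evaluated.grid.spacing_mm[ax]
        if r_hi < e_lo or e_hi < r_lo:
            raise ValueError("reference and evaluated grids do not overlap")
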