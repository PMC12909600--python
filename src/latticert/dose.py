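"""Deterministic dose painter standing in for a treatment-planning optimizer.

The painter is openly a geometric stand-in, not a beam model: it constructs
dose fields from radial kernels and hard caps so that, on well-formed
geometries, the painted plans satisfy the planning objectives by
construction (lattice spheres at the boost level, a uniform low-dose bath in
PTV_Low, Gaussian penumbra falloff outside, normal-tissue ring capped).
No claim of physical realism is made; realism lives entirely in the
evaluation stack, which is engine-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DoseGrid, StructureMask, accumulate  # noqa: F401  (re-export)
from .lattice import SphereSet

__all__ = [
    "RegimenSpec",
    "PainterParams",
    "PlanConstructionError",
    "paint_phase1",
    "paint_phase2",
    "accumulate",
]


@dataclass(frozen=True)
class RegimenSpec:
    """The two-phase prescription.

    Phase 1 delivers ``phase1_sphere_dose_gy`` (12 Gy) to the high-dose
    sphere lattice and ``phase1_gtv_dose_gy`` (4 Gy) to the GTV/PTV_Low
    bath; Phase 2 adds ``phase2_n_fractions`` fractions of
    ``phase2_fraction_dose_gy`` (4 × 4 Gy) to PTV_Low, totalling 20 Gy to
    the low-dose target at defaults. Hotspots are capped at
    ``hotspot_cap_gy`` (15 Gy = 125 % of the sphere dose).
    """

    phase1_sphere_dose_gy: float = 12.0
    phase1_gtv_dose_gy: float = 4.0
    phase2_fraction_dose_gy: float = 4.0
    phase2_n_fractions: int = 4
    hotspot_cap_gy: float = 15.0

    def __post_init__(self):
        if self.hotspot_cap_gy < self.phase1_sphere_dose_gy:
            raise ValueError("hotspot_cap_gy must be >= phase1_sphere_dose_gy")
        if min(self.phase1_sphere_dose_gy, self.phase1_gtv_dose_gy,
               self.phase2_fraction_dose_gy) < 0 or self.phase2_n_fractions < 0:
            raise ValueError("doses and fraction counts must be non-negative")

    @property
    def total_low_dose_gy(self) -> float:
        return self.phase1_gtv_dose_gy + \
            self.phase2_fraction_dose_gy * self.phase2_n_fractions


@dataclass(frozen=True)
class PainterParams:
    """Kernel parameters of the stand-in painter.

    ``penumbra_sigma_mm`` sets the Gaussian falloff of the low-dose bath
    outside PTV_Low. ``boost_kernel_sigma_mm`` sets the falloff of each
    sphere's boost outside its surface; it is kept tight (2.5 mm) so that
    the summed boost penumbra stays within the PTV_Low mean-dose budget
    even for densely packed lattices in large targets. ``ring_cap_gy`` is
    the hard cap applied everywhere outside PTV_Low.
    """

    penumbra_sigma_mm: float = 4.0
    boost_kernel_sigma_mm: float = 2.5
    ring_cap_gy: float = 4.0

    def __post_init__(self):
        if min(self.penumbra_sigma_mm, self.boost_kernel_sigma_mm,
               self.ring_cap_gy) <= 0:
            raise ValueError("painter parameters must be positive")


class PlanConstructionError(RuntimeError):
    """The requested objectives are unsatisfiable for this geometry."""


def _base_component(ptv_low: StructureMask, level_gy: float,
                    params: PainterParams) -> np.ndarray:
    """Uniform ``level_gy`` inside PTV_Low, Gaussian falloff outside,
    hard-capped at ``ring_cap_gy`` outside PTV_Low."""
    occ = ptv_low.occupancy
    dose = np.full(ptv_low.grid.dims, float(level_gy))
    if not occ.all():
        dist = ndimage.distance_transform_edt(~occ, sampling=ptv_low.grid.spacing_mm)
        outside = ~occ
        fall = level_gy * np.exp(-0.5 * (dist[outside] / params.penumbra_sigma_mm) ** 2)
        dose[outside] = np.minimum(fall, params.ring_cap_gy)
    return dose


def _boost_component(spheres: SphereSet, grid, level_gy: float,
                     sigma_mm: float) -> np.ndarray:
    """Voxelwise max of per-sphere kernels: flat ``level_gy`` inside each
    sphere, Gaussian tail outside its surface, truncated at 5 sigma."""
    boost = np.zeros(grid.dims)
    cutoff = spheres.radius_mm + 5.0 * sigma_mm
    for c in spheres.centers_mm:
        lo = np.floor(grid.world_to_index(np.asarray(c) - cutoff)).astype(int)
        hi = np.ceil(grid.world_to_index(np.asarray(c) + cutoff)).astype(int) + 1
        lo = np.clip(lo, 0, grid.dims)
        hi = np.clip(hi, 0, grid.dims)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        coords = [grid.axis_coords(ax)[sl[ax]] - c[ax] for ax in range(3)]
        r = np.sqrt(
            coords[0][:, None, None] ** 2
            + coords[1][None, :, None] ** 2
            + coords[2][None, None, :] ** 2
        )
        excess = np.maximum(r - spheres.radius_mm, 0.0)
        kernel = level_gy * np.exp(-0.5 * (excess / sigma_mm) ** 2)
        kernel[excess > 5.0 * sigma_mm] = 0.0
        np.maximum(boost[sl], kernel, out=boost[sl])
    return boost


def paint_phase1(structures: dict[str, StructureMask], spheres: SphereSet,
                 regimen: RegimenSpec = RegimenSpec(),
                 params: PainterParams = PainterParams()) -> DoseGrid:
    """Paint the Phase 1 lattice plan: 12 Gy spheres on a 4 Gy GTV bath.

    ``structures`` must contain ``GTV`` and ``PTV_Low`` masks on one grid
    (an empty sphere set yields the pure bath plan). The field is the
    voxelwise maximum of the bath and the sphere boosts inside the GTV, and
    the capped bath alone outside, so the ring cap can never be breached by
    boost spill.

    Raises
    ------
    PlanConstructionError
        If any kept sphere reaches within one boost sigma of the PTV_Low
        boundary (its penumbra could not be contained), or the construction
        exceeds the hotspot cap.
    """
    gtv = structures["GTV"]
    ptv_low = structures["PTV_Low"]
    gtv.grid.require_same(ptv_low.grid, "paint_phase1")

    base = _base_component(ptv_low, regimen.phase1_gtv_dose_gy, params)

    if len(spheres) > 0:
        dist_out = ndimage.distance_transform_edt(
            ptv_low.occupancy, sampling=ptv_low.grid.spacing_mm
        )
        for c in spheres.centers_mm:
            ci = np.round(ptv_low.grid.world_to_index(c)).astype(int)
            if (np.any(ci < 0) or np.any(ci >= ptv_low.grid.dims)
                    or not ptv_low.occupancy[tuple(ci)]):
                raise PlanConstructionError(
                    f"sphere center {tuple(np.round(c, 1))} lies outside PTV_Low"
                )
            clearance = float(dist_out[tuple(ci)]) - spheres.radius_mm
            if clearance < params.boost_kernel_sigma_mm:
                raise PlanConstructionError(
                    f"sphere at {tuple(np.round(c, 1))} is within one boost sigma "
                    f"({params.boost_kernel_sigma_mm} mm) of the PTV_Low boundary; "
                    "boost penumbra cannot be contained"
                )
        boost = _boost_component(
            spheres, gtv.grid, regimen.phase1_sphere_dose_gy,
            params.boost_kernel_sigma_mm,
        )
        dose = np.where(gtv.occupancy, np.maximum(base, boost), base)
    else:
        dose = base

    if dose.max() > regimen.hotspot_cap_gy + 1e-9:
        raise PlanConstructionError(
            f"constructed max dose {dose.max():.2f} Gy exceeds the hotspot cap "
            f"{regimen.hotspot_cap_gy} Gy"
        )
    return DoseGrid(gtv.grid, dose, phase_label="phase1")


def paint_phase2(structures: dict[str, StructureMask],
                 regimen: RegimenSpec = RegimenSpec(),
                 params: PainterParams = PainterParams()) -> DoseGrid:
    """Paint one uniform Phase 2 fraction: 4 Gy to PTV_Low with capped
    penumbra falloff outside."""
    ptv_low = structures["PTV_Low"]
    if ptv_low.is_empty:
        raise PlanConstructionError("paint_phase2 requires a non-empty PTV_Low")
    dose = _base_component(ptv_low, regimen.phase2_fraction_dose_gy, params)
    return DoseGrid(ptv_low.grid, dose, phase_label="phase2_fraction")
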