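"""Margin operations on structure masks via exact Euclidean distance transforms.

Uniform expansions and retractions are computed from the exact EDT with the
grid's physical sampling, so margins stay isotropic in millimetres even on
anisotropic grids (structuring-element dilation would not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import StructureMask

__all__ = ["DerivationSpec", "expand", "retract", "derive_structures"]


@dataclass(frozen=True)
class DerivationSpec:
    """Margins (mm) used to derive the planning structures from the GTV.

    ``ptv_low_margin_mm`` is the uniform GTV→PTV_Low expansion (clinically
    3–5 mm; default the upper end). ``ptv_high_retraction_mm`` is the GTV
    retraction inside which lattice spheres must lie. ``ring_margin_mm`` is
    the outer extent of the normal-tissue ring beyond PTV_Low.
    """

    ptv_low_margin_mm: float = 5.0
    ptv_high_retraction_mm: float = 10.0
    ring_margin_mm: float = 30.0

    def __post_init__(self):
        for f in ("ptv_low_margin_mm", "ptv_high_retraction_mm", "ring_margin_mm"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def expand(mask: StructureMask, margin_mm: float, name: str | None = None,
           role: str | None = None) -> StructureMask:
    """Uniform expansion: occupied iff Euclidean distance to the nearest
    occupied voxel center is <= ``margin_mm``. ``expand(m, 0) == m``.

    The result is implicitly clipped to the grid; if the true expansion
    would extend past the grid bounds a warning is issued.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    occ = mask.occupancy
    if margin_mm == 0 or not occ.any():
        out = occ.copy()
    else:
        dist = ndimage.distance_transform_edt(~occ, sampling=mask.grid.spacing_mm)
        out = dist <= margin_mm
        edge = np.zeros_like(out)
        for ax in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[ax] = end
                edge[tuple(sl)] = True
        if (out & edge).any():
            warnings.warn(
                f"expansion of {mask.name!r} by {margin_mm} mm reaches the grid "
                "boundary and is clipped",
                stacklevel=2,
            )
    return StructureMask(mask.grid, name or mask.name, role or mask.role, out)


def retract(mask: StructureMask, margin_mm: float, name: str | None = None,
            role: str | None = None) -> StructureMask:
    """Uniform retraction: occupied iff occupied in the input and the distance
    to the nearest unoccupied voxel center is > ``margin_mm``.

    ``retract(m, 0) == m``; retraction may legitimately empty the mask.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    occ = mask.occupancy
    if margin_mm == 0 or not occ.any():
        out = occ.copy()
    else:
        dist = ndimage.distance_transform_edt(occ, sampling=mask.grid.spacing_mm)
        out = occ & (dist > margin_mm)
        if not out.any():
            warnings.warn(
                f"retraction of {mask.name!r} by {margin_mm} mm is empty",
                stacklevel=2,
            )
    return StructureMask(mask.grid, name or mask.name, role or mask.role, out)


def derive_structures(gtv: StructureMask, body: StructureMask,
                      spheres, spec: DerivationSpec = DerivationSpec()):
    """Derive PTV_Low, PTV_High and the normal-tissue ring from the GTV.

    PTV_Low = expand(GTV, margin) ∩ Body; PTV_High = lattice spheres kept
    after cropping to the retracted GTV; Ring = (expand(PTV_Low, 30 mm) −
    PTV_Low) ∩ Body.

    Parameters
    ----------
    spheres : SphereSet or StructureMask
        The uniform high-dose lattice (pre-crop).

    Returns
    -------
    dict with keys ``PTV_Low``, ``PTV_High``, ``Ring``, ``kept_spheres``,
    ``removed_spheres``.
    """
    from .lattice import crop_to_ptv_high

    gtv.grid.require_same(body.grid, "derive_structures")
    if (gtv.occupancy & ~body.occupancy).any():
        raise ValueError("GTV must be contained in Body")

    ptv_low = expand(gtv, spec.ptv_low_margin_mm, name="PTV_Low", role="PTV_Low")
    ptv_low = ptv_low.with_occupancy(ptv_low.occupancy & body.occupancy)

    ptv_high, kept, removed = crop_to_ptv_high(
        spheres, gtv, retraction_mm=spec.ptv_high_retraction_mm
    )

    shell = expand(ptv_low, spec.ring_margin_mm, name="Ring", role="Ring")
    ring = shell.with_occupancy(shell.occupancy & ~ptv_low.occupancy & body.occupancy)

    if (ptv_high.occupancy & ~gtv.occupancy).any():
        raise ValueError("internal consistency: PTV_High must lie inside the GTV")
    if (gtv.occupancy & ~ptv_low.occupancy).any():
        raise ValueError("internal consistency: GTV must lie inside PTV_Low")
    if (ring.occupancy & ptv_low.occupancy).any():
        raise ValueError("internal consistency: Ring overlaps PTV_Low")

    return {
        "PTV_Low": ptv_low,
        "PTV_High": ptv_high,
        "Ring": ring,
        "kept_spheres": kept,
        "removed_spheres": removed,
    }
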