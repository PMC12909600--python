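"""Synthetic patient generator: body contours, GTVs and organs at risk.

Emulates the geometric character of the clinical cohort (five thoracic and
five extremity sarcoma-like cases) on a regular millimetre-scale grid so
every pipeline stage runs with no external data. Bodies are elliptic
cylinders (thorax) or narrow tapered cylinders (extremity — deliberately
slim so the 3 cm normal-tissue ring is clipped by the body contour); GTVs
are smooth ellipsoids or lobed unions of ellipsoids 4–12 cm in extent; one
or two OAR solids sit a configurable offset away. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import (Ellipsoid, LobedSolid, StructureMask, VoxelGrid,
                   voxelize_solid)
from .io import StructureSetManifest

__all__ = ["CaseSpec", "SyntheticCase", "generate_case", "generate_cohort",
           "perturb_contour"]

SITES = ("thorax", "extremity")
GTV_SHAPES = ("ellipsoid", "lobed")

# Site-dependent sampling ranges for the GTV extent (mm per axis).
_EXTENT_RANGE = {"thorax": (60.0, 120.0), "extremity": (40.0, 80.0)}


@dataclass(frozen=True)
class CaseSpec:
    """Specification of one synthetic case.

    ``gtv_extent_mm`` may be None (extents are then drawn from the
    site-dependent range) or a per-axis triple in [40, 120] mm.
    """

    site: str = "thorax"
    gtv_shape: str = "ellipsoid"
    gtv_extent_mm: tuple[float, float, float] | None = None
    oar_offset_mm: float = 20.0
    spacing_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        if self.gtv_shape not in GTV_SHAPES:
            raise ValueError(f"gtv_shape must be one of {GTV_SHAPES}")
        if self.gtv_extent_mm is not None:
            ext = tuple(float(v) for v in self.gtv_extent_mm)
            if any(not 40.0 <= e <= 120.0 for e in ext):
                raise ValueError("gtv_extent_mm entries must lie in [40, 120] mm")
            object.__setattr__(self, "gtv_extent_mm", ext)


@dataclass
class SyntheticCase:
    case_id: str
    spec: CaseSpec
    grid: VoxelGrid
    masks: dict[str, StructureMask]

    def manifest(self) -> StructureSetManifest:
        entries = [
            {"name": name, "role": m.role, "file": f"{name}.nrrd"}
            for name, m in self.masks.items()
        ]
        return StructureSetManifest(
            case_id=self.case_id, entries=entries,
            prescription={"phase1_sphere_dose_gy": 12.0,
                          "phase1_gtv_dose_gy": 4.0,
                          "phase2_fraction_dose_gy": 4.0,
                          "phase2_n_fractions": 4},
            grid=self.grid,
        )


def _body_half_extents(site: str, gtv_ext: np.ndarray) -> tuple[float, float, float]:
    if site == "thorax":
        return (95.0, 75.0, gtv_ext[2] / 2 + 50.0)
    # extremity: narrow limb cross-section, capped so large tumours do not fit
    r = min(55.0, max(45.0, gtv_ext[:2].max() / 2 + 12.0))
    return (r, r, gtv_ext[2] / 2 + 50.0)


def generate_case(spec: CaseSpec, case_id: str | None = None) -> SyntheticCase:
    """Generate Body, GTV and OAR masks for one case, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)

    if spec.gtv_extent_mm is None:
        lo, hi = _EXTENT_RANGE[spec.site]
        ext = rng.uniform(lo, hi, size=3)
    else:
        ext = np.asarray(spec.gtv_extent_mm, dtype=float)
    semi = ext / 2.0

    body_half = np.asarray(_body_half_extents(spec.site, ext))
    if np.any(semi + 8.0 > body_half):
        raise ValueError(
            f"GTV extent {ext.round(1).tolist()} mm too large for a "
            f"{spec.site} body of half-extents {body_half.round(1).tolist()} mm"
        )

    s = spec.spacing_mm
    pad = 3 * s
    dims = tuple(int(np.ceil((2 * h + 2 * pad) / s)) + 1 for h in body_half)
    origin = tuple(-(d - 1) * s / 2.0 for d in dims)
    grid = VoxelGrid(origin, (s, s, s), dims)
    x, y, z = grid.coordinate_arrays()

    # Body: elliptic cylinder (thorax) or tapered circular cylinder (extremity)
    if spec.site == "thorax":
        body_occ = ((x / body_half[0]) ** 2 + (y / body_half[1]) ** 2 <= 1.0) \
            & (np.abs(z) <= body_half[2])
    else:
        taper = 1.0 - 0.15 * (z + body_half[2]) / (2 * body_half[2])
        r_z = body_half[0] * taper
        body_occ = (x ** 2 + y ** 2 <= r_z ** 2) & (np.abs(z) <= body_half[2])
    body = StructureMask(grid, "Body", "Body", np.broadcast_to(
        body_occ, grid.dims).copy())

    # GTV: centered ellipsoid, or a smoothed union of 2-3 offset lobes
    if spec.gtv_shape == "ellipsoid":
        solid = Ellipsoid((0.0, 0.0, 0.0), tuple(semi))
    else:
        n_lobes = int(rng.integers(2, 4))
        lobes = [Ellipsoid((0.0, 0.0, 0.0), tuple(semi * 0.85))]
        for _ in range(n_lobes - 1):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * semi * 0.45
            lobe_semi = semi * rng.uniform(0.5, 0.7)
            lobes.append(Ellipsoid(tuple(offset), tuple(lobe_semi)))
        solid = LobedSolid(tuple(lobes), smoothing_mm=4.0)
    gtv = voxelize_solid(solid, grid, name="GTV", role="GTV")

    if (gtv.occupancy & ~body.occupancy).any():
        raise ValueError("generated GTV is not strictly inside the body")

    masks = {"Body": body, "GTV": gtv}

    # OARs: 1-2 small solids offset laterally from the GTV surface
    n_oars = int(rng.integers(1, 3))
    for i in range(n_oars):
        sign = 1.0 if i % 2 == 0 else -1.0
        cx = sign * (semi[0] + spec.oar_offset_mm + 8.0)
        oar_solid = Ellipsoid((cx, 0.0, 0.0), (8.0, 8.0, min(40.0, body_half[2] - 5)))
        occ = oar_solid.inside(grid) & body.occupancy
        if occ.any():
            masks[f"OAR_{i + 1}"] = StructureMask(grid, f"OAR_{i + 1}", "OAR", occ)

    return SyntheticCase(case_id or f"{spec.site}_{spec.seed:04d}", spec, grid, masks)


def generate_cohort(n_thorax: int = 5, n_extremity: int = 5,
                    master_seed: int = 42, spacing_mm: float = 2.0,
                    gtv_shapes: tuple[str, ...] = ("ellipsoid", "lobed"),
                    ) -> list[SyntheticCase]:
    """Generate the default cohort: independently seeded thorax and
    extremity cases (5 + 5 by default), alternating GTV shapes."""
    if n_thorax < 0 or n_extremity < 0:
        raise ValueError("cohort counts must be >= 0")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_thorax + n_extremity)]
    cases = []
    sites = ["thorax"] * n_thorax + ["extremity"] * n_extremity
    for i, (site, seed) in enumerate(zip(sites, seeds)):
        shape = gtv_shapes[i % len(gtv_shapes)]
        spec = CaseSpec(site=site, gtv_shape=shape, spacing_mm=spacing_mm,
                        seed=seed)
        cases.append(generate_case(spec, case_id=f"case{i + 1:02d}_{site}"))
    return cases


def perturb_contour(gtv: StructureMask, magnitude_mm: float,
                    seed: int = 0, correlation_mm: float = 12.0) -> StructureMask:
    """Smooth random boundary displacement with RMS ~ ``magnitude_mm``.

    The mask's signed distance field is perturbed by a smooth Gaussian
    random field (correlation length ``correlation_mm``) normalised to the
    requested RMS and re-thresholded at zero; because the signed distance
    has unit gradient near the boundary, the surface displaces locally by
    about the field value. Emulates inter-observer recontouring for
    exercising Dice/MSD verification. ``magnitude_mm = 0`` is the identity.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if magnitude_mm == 0:
        return gtv.with_occupancy(gtv.occupancy.copy())
    spacing = gtv.grid.spacing_mm
    # signed distance to the structure surface: the voxel-center EDT is offset
    # by half a voxel so boundary-adjacent centers sit at ~±spacing/2, not ±spacing
    half = float(np.mean(spacing)) / 2.0
    d_out = ndimage.distance_transform_edt(~gtv.occupancy, sampling=spacing)
    d_in = ndimage.distance_transform_edt(gtv.occupancy, sampling=spacing)
    sd = np.where(gtv.occupancy, -(d_in - half), d_out - half)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(gtv.grid.dims)
    sigma_vox = [correlation_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    f *= magnitude_mm / np.sqrt(np.mean(f ** 2))
    return gtv.with_occupancy(sd <= f, name=f"{gtv.name}_recontoured")
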