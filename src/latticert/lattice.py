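"""High-dose sphere-lattice generation and GTV-based cropping.

A uniform simple-cubic matrix of 1 cm spheres spaced 2 cm center-to-center
is generated about a chosen center point, voxelized, and cropped so that
only spheres lying (essentially) wholly inside a 1 cm retraction of the GTV
survive; the union of the survivors is the high-dose planning target
PTV_High.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Sphere, StructureMask, VoxelGrid
from .margins import retract

__all__ = [
    "LatticeSpec",
    "SphereSet",
    "generate_lattice",
    "voxelize_lattice",
    "crop_to_ptv_high",
    "lattice_spec_for_gtv",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of the uniform sphere matrix.

    Defaults are the clinical template: 1 cm diameter spheres, 2 cm
    center-to-center, in a 20 cm cubic matrix (expandable to 30 cm for
    large targets) positioned about ``center_point_mm``.
    """

    sphere_diameter_mm: float = 10.0
    center_spacing_mm: float = 20.0
    matrix_extent_mm: tuple[float, float, float] = (200.0, 200.0, 200.0)
    center_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        ext = np.asarray(self.matrix_extent_mm, dtype=float).reshape(-1)
        if ext.size == 1:
            ext = np.repeat(ext, 3)
        object.__setattr__(self, "matrix_extent_mm", tuple(ext.tolist()))
        cp = tuple(float(v) for v in np.asarray(self.center_point_mm).reshape(3))
        object.__setattr__(self, "center_point_mm", cp)
        if self.sphere_diameter_mm <= 0:
            raise ValueError("sphere_diameter_mm must be positive")
        if self.center_spacing_mm < self.sphere_diameter_mm:
            raise ValueError(
                "center_spacing_mm must be >= sphere_diameter_mm (spheres overlap)"
            )
        if any(e <= 0 for e in self.matrix_extent_mm):
            raise ValueError("matrix_extent_mm must be positive")


@dataclass
class SphereSet:
    """A set of equal-radius spheres given by their world-space centers."""

    centers_mm: np.ndarray = field(repr=False)  # (n, 3)
    radius_mm: float = 5.0
    provenance: str = "raw_lattice"  # or "cropped"

    def __post_init__(self):
        c = np.asarray(self.centers_mm, dtype=float).reshape(-1, 3)
        self.centers_mm = c

    def __len__(self) -> int:
        return self.centers_mm.shape[0]

    def spheres(self) -> list[Sphere]:
        return [Sphere(tuple(c), self.radius_mm) for c in self.centers_mm]

    def min_center_spacing_mm(self) -> float:
        """Minimum pairwise center-to-center distance (inf for < 2 spheres)."""
        from scipy.spatial.distance import pdist

        if len(self) < 2:
            return float("inf")
        return float(pdist(self.centers_mm).min())


def generate_lattice(spec: LatticeSpec) -> SphereSet:
    """Generate a simple-cubic lattice of sphere centers about the center point.

    Planes are placed at integer multiples of the spacing, symmetric about
    ``center_point_mm``, using the smallest symmetric set of planes that
    covers the full matrix extent (boundary planes included): per axis,
    offsets ``-k..k`` with ``k = ceil(extent / (2 * spacing))``.
    """
    step = spec.center_spacing_mm
    axes = []
    for ax in range(3):
        k = int(np.ceil(spec.matrix_extent_mm[ax] / (2.0 * step) - 1e-12))
        axes.append(spec.center_point_mm[ax] + step * np.arange(-k, k + 1))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return SphereSet(centers, radius_mm=spec.sphere_diameter_mm / 2.0,
                     provenance="raw_lattice")


def lattice_spec_for_gtv(gtv: StructureMask, sphere_diameter_mm: float = 10.0,
                         center_spacing_mm: float = 20.0) -> LatticeSpec:
    """Template lattice for a GTV: centered on its centroid, with the smallest
    default matrix extent (200 or 300 mm) exceeding the GTV bounding box by
    at least one spacing on every axis."""
    idx = np.argwhere(gtv.occupancy)
    if idx.size == 0:
        raise ValueError("cannot size a lattice for an empty GTV")
    lo = gtv.grid.index_to_world(idx.min(axis=0))
    hi = gtv.grid.index_to_world(idx.max(axis=0))
    need = float((hi - lo).max()) + center_spacing_mm
    extent = 200.0 if need <= 200.0 else 300.0
    return LatticeSpec(
        sphere_diameter_mm=sphere_diameter_mm,
        center_spacing_mm=center_spacing_mm,
        matrix_extent_mm=(extent, extent, extent),
        center_point_mm=tuple(gtv.centroid_mm()),
    )


def _sphere_occupancy_local(center, radius, grid: VoxelGrid):
    """Boolean occupancy of one sphere restricted to its bounding subgrid.

    Returns (slices, local boolean array); the subgrid may be empty when the
    sphere lies outside the grid.
    """
    lo_i = np.floor(grid.world_to_index(np.asarray(center) - radius)).astype(int)
    hi_i = np.ceil(grid.world_to_index(np.asarray(center) + radius)).astype(int) + 1
    lo_i = np.clip(lo_i, 0, grid.dims)
    hi_i = np.clip(hi_i, 0, grid.dims)
    if np.any(lo_i >= hi_i):
        return None, None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo_i, hi_i))
    coords = [
        grid.axis_coords(ax)[sl[ax]] - center[ax]
        for ax in range(3)
    ]
    r2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    return sl, r2 <= radius ** 2


def voxelize_lattice(spheres: SphereSet, grid: VoxelGrid,
                     name: str = "_SpheresMatrix") -> StructureMask:
    """Voxelize a sphere set as the union of voxel-center-inclusion spheres."""
    occ = np.zeros(grid.dims, dtype=bool)
    for c in spheres.centers_mm:
        sl, local = _sphere_occupancy_local(c, spheres.radius_mm, grid)
        if sl is not None:
            occ[sl] |= local
    return StructureMask(grid, name, "SpheresMatrix", occ)


def crop_to_ptv_high(matrix, gtv: StructureMask, retraction_mm: float = 10.0,
                     completeness_tol: float = 0.95):
    """Crop the sphere matrix to the retracted GTV and build PTV_High.

    The GTV is retracted by ``retraction_mm`` (so surviving spheres keep at
    least that clearance from the GTV surface); each sphere is kept only if
    at least ``completeness_tol`` of its voxels survive the intersection —
    automating the clinical deletion of partially cropped spheres. PTV_High
    is the union of the kept spheres' full voxelizations.

    Parameters
    ----------
    matrix : SphereSet or StructureMask
        The uncropped lattice. A StructureMask is decomposed into individual
        spheres by connected-component labelling (valid because the lattice
        spacing is at least one diameter, so spheres are disjoint).

    Returns
    -------
    (ptv_high, kept, removed) : (StructureMask, SphereSet, SphereSet)
    """
    if retraction_mm < 0:
        raise ValueError("retraction_mm must be >= 0")
    if not 0 < completeness_tol <= 1:
        raise ValueError("completeness_tol must be in (0, 1]")
    if gtv.is_empty:
        raise ValueError("crop_to_ptv_high requires a non-empty GTV")

    grid = gtv.grid
    spheres = _as_sphere_set(matrix, grid)
    allowed = retract(gtv, retraction_mm, name="GTV_retracted").occupancy

    ptv = np.zeros(grid.dims, dtype=bool)
    kept_idx, removed_idx = [], []
    for i, c in enumerate(spheres.centers_mm):
        sl, local = _sphere_occupancy_local(c, spheres.radius_mm, grid)
        n_total = int(local.sum()) if sl is not None else 0
        n_survive = int((local & allowed[sl]).sum()) if sl is not None else 0
        if n_total > 0 and n_survive >= completeness_tol * n_total:
            kept_idx.append(i)
            ptv[sl] |= local
        else:
            removed_idx.append(i)

    kept = SphereSet(spheres.centers_mm[kept_idx], spheres.radius_mm, "cropped")
    removed = SphereSet(spheres.centers_mm[removed_idx], spheres.radius_mm, "cropped")
    if len(kept) == 0:
        warnings.warn(
            "no lattice sphere survives the GTV retraction; PTV_High is empty "
            "(expected for small or irregular tumours)",
            stacklevel=2,
        )
    ptv_high = StructureMask(grid, "PTV_High", "PTV_High", ptv)
    return ptv_high, kept, removed


def _as_sphere_set(matrix, grid: VoxelGrid) -> SphereSet:
    if isinstance(matrix, SphereSet):
        return matrix
    if isinstance(matrix, StructureMask):
        from scipy import ndimage

        matrix.grid.require_same(grid, "crop_to_ptv_high")
        labels, n = ndimage.label(matrix.occupancy)
        if n == 0:
            return SphereSet(np.empty((0, 3)), 5.0, "raw_lattice")
        centers_idx = ndimage.center_of_mass(matrix.occupancy, labels, range(1, n + 1))
        centers = np.array([grid.index_to_world(ci) for ci in centers_idx])
        # recover the common radius from the mean component volume
        vols = ndimage.sum_labels(matrix.occupancy, labels, range(1, n + 1))
        r = float((3.0 * vols.mean() * grid.voxel_volume_mm3 / (4.0 * np.pi)) ** (1 / 3))
        return SphereSet(centers, r, "raw_lattice")
    raise TypeError(f"matrix must be SphereSet or StructureMask, got {type(matrix)}")
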