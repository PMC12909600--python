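"""Voxel-grid data model: grids, structure masks, dose grids, analytic solids.

All spatial quantities are world coordinates in millimetres on axis-aligned
regular grids. Arrays are indexed ``(i, j, k)`` along ``(x, y, z)``, 0-based,
with the voxel-center convention: voxel ``(i, j, k)`` has its center at
``origin + index * spacing`` on each axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "DoseGrid",
    "Sphere",
    "Ellipsoid",
    "LobedSolid",
    "voxelize_solid",
    "GridMismatchError",
    "ROLES",
]

ROLES = ("GTV", "SpheresMatrix", "PTV_High", "PTV_Low", "Ring", "OAR", "Body")

_GEOM_ATOL = 1e-6  # mm tolerance when comparing grid geometry


class GridMismatchError(ValueError):
    """Raised when an operation requires identical grids but geometry differs."""


def _as_triple(x, dtype=float) -> tuple:
    arr = np.asarray(x, dtype=dtype).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"expected scalar or length-3 sequence, got {x!r}")
    return tuple(arr.tolist())


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned 3D grid geometry shared by masks and doses.

    Parameters
    ----------
    origin_mm : world position (mm) of the center of voxel ``(0, 0, 0)``.
    spacing_mm : per-axis voxel edge length in mm, strictly positive.
    dims : per-axis voxel counts, positive integers.
    """

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin_mm", _as_triple(self.origin_mm))
        object.__setattr__(self, "spacing_mm", _as_triple(self.spacing_mm))
        object.__setattr__(self, "dims", _as_triple(self.dims, dtype=int))
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.dims[axis]) * self.spacing_mm[axis]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1)/(1,ny,1)/(1,1,nz) world-coordinate arrays."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, pos) -> np.ndarray:
        """Continuous (fractional) index of a world point."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_geometry(self, other: "VoxelGrid", atol: float = _GEOM_ATOL) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
        )

    def require_same(self, other: "VoxelGrid", what: str = "operation") -> None:
        if not self.same_geometry(other):
            raise GridMismatchError(
                f"{what} requires identical grids: "
                f"{self.dims}@{self.spacing_mm} vs {other.dims}@{other.spacing_mm}"
            )


@dataclass
class StructureMask:
    """Binary occupancy on a :class:`VoxelGrid` with a named clinical role."""

    grid: VoxelGrid
    name: str
    role: str
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != tuple(self.grid.dims):
            raise ValueError(
                f"occupancy shape {occ.shape} != grid dims {self.grid.dims}"
            )
        self.occupancy = occ

    @property
    def volume_cc(self) -> float:
        return float(self.occupancy.sum()) * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def centroid_mm(self) -> np.ndarray:
        """World-coordinate centroid of occupied voxel centers."""
        if self.is_empty:
            raise ValueError(f"centroid of empty mask {self.name!r}")
        idx = np.argwhere(self.occupancy).mean(axis=0)
        return self.grid.index_to_world(idx)

    def with_occupancy(self, occ: np.ndarray, name: str | None = None,
                       role: str | None = None) -> "StructureMask":
        return StructureMask(self.grid, name or self.name, role or self.role, occ)


@dataclass
class DoseGrid:
    """Scalar absorbed dose in Gy per voxel on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose_gy: np.ndarray = field(repr=False)
    phase_label: str = "phase1"

    def __post_init__(self):
        d = np.asarray(self.dose_gy, dtype=np.float64)
        if d.shape != tuple(self.grid.dims):
            raise ValueError(f"dose shape {d.shape} != grid dims {self.grid.dims}")
        if np.any(d < 0):
            raise ValueError("dose_gy must be non-negative everywhere")
        self.dose_gy = d

    @property
    def max_gy(self) -> float:
        return float(self.dose_gy.max())


# ---------------------------------------------------------------------------
# Analytic solids and voxelization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float

    def inside(self, grid: VoxelGrid) -> np.ndarray:
        if self.radius_mm <= 0:
            return np.zeros(grid.dims, dtype=bool)
        x, y, z = grid.coordinate_arrays()
        cx, cy, cz = self.center_mm
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius_mm ** 2


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def inside(self, grid: VoxelGrid) -> np.ndarray:
        if any(a <= 0 for a in self.semi_axes_mm):
            return np.zeros(grid.dims, dtype=bool)
        x, y, z = grid.coordinate_arrays()
        cx, cy, cz = self.center_mm
        ax, ay, az = self.semi_axes_mm
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class LobedSolid:
    """Union of overlapping ellipsoids with distance-field boundary smoothing.

    Emulates a multi-lobed tumour: the hard union of the lobes is converted
    to a signed distance field, smoothed with a Gaussian of ``smoothing_mm``,
    and re-thresholded at zero. ``smoothing_mm = 0`` gives the plain union.
    """

    lobes: tuple[Ellipsoid, ...]
    smoothing_mm: float = 4.0

    def inside(self, grid: VoxelGrid) -> np.ndarray:
        from scipy import ndimage

        union = np.zeros(grid.dims, dtype=bool)
        for lobe in self.lobes:
            union |= lobe.inside(grid)
        if self.smoothing_mm <= 0 or not union.any() or union.all():
            return union
        sampling = grid.spacing_mm
        sd = ndimage.distance_transform_edt(~union, sampling=sampling) - \
            ndimage.distance_transform_edt(union, sampling=sampling)
        sigma_vox = [self.smoothing_mm / s for s in sampling]
        return ndimage.gaussian_filter(sd, sigma=sigma_vox) <= 0.0


def voxelize_solid(solid, grid: VoxelGrid, name: str = "solid",
                   role: str = "GTV") -> StructureMask:
    """Voxelize an analytic solid: a voxel is occupied iff its center lies inside.

    An empty result (solid outside the grid or degenerate) warns but does
    not fail.
    """
    occ = solid.inside(grid)
    if not occ.any():
        warnings.warn(
            f"voxelize_solid: {name!r} produced an empty mask "
            "(solid degenerate or entirely outside grid)",
            stacklevel=2,
        )
    return StructureMask(grid, name, role, occ)


def accumulate(doses: Sequence[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of dose grids on a common grid, labelled ``total``."""
    if not doses:
        raise ValueError("accumulate requires at least one DoseGrid")
    ref = doses[0]
    total = np.zeros(ref.grid.dims, dtype=np.float64)
    for d in doses:
        ref.grid.require_same(d.grid, "dose accumulation")
        total += d.dose_gy
    return DoseGrid(ref.grid, total, phase_label="total")
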