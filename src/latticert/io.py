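"""File I/O for masks, doses and the structure-set manifest.

Masks and doses are stored one structure per file as NRRD (preferred) or
NIfTI-1, through SimpleITK. Only axis-aligned (identity direction matrix)
grids are supported; world coordinates are taken verbatim from the file
header with no LPS/RAS reinterpretation. The manifest is a JSON file listing
``case_id``, the common grid, and the structure entries with their roles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grid import DoseGrid, GridMismatchError, StructureMask, VoxelGrid

__all__ = [
    "read_mask",
    "write_mask",
    "read_dose",
    "write_dose",
    "StructureSetManifest",
    "read_manifest",
    "write_manifest",
    "load_case_masks",
    "UnsupportedOrientationError",
]

_FORMATS = {".nrrd": "NRRD", ".nii": "NIfTI", ".nii.gz": "NIfTI"}


class UnsupportedOrientationError(ValueError):
    """File declares a non-axis-aligned direction matrix."""


def _check_format(path: Path) -> None:
    suffixes = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffixes not in _FORMATS:
        raise ValueError(f"unsupported file format {path.name!r}; use NRRD or NIfTI")


def _grid_from_image(img: sitk.Image) -> VoxelGrid:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedOrientationError(
            f"non-axis-aligned direction matrix {direction.tolist()} is not supported"
        )
    return VoxelGrid(tuple(img.GetOrigin()), tuple(img.GetSpacing()), tuple(img.GetSize()))


def _image_from_array(arr: np.ndarray, grid: VoxelGrid) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]; ours are [x, y, z].
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetOrigin(tuple(float(v) for v in grid.origin_mm))
    img.SetSpacing(tuple(float(v) for v in grid.spacing_mm))
    return img


def _array_from_image(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def write_mask(mask: StructureMask, path: str | os.PathLike) -> None:
    path = Path(path)
    _check_format(path)
    img = _image_from_array(mask.occupancy.astype(np.uint8), mask.grid)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask(path: str | os.PathLike, name: str | None = None,
              role: str = "GTV") -> StructureMask:
    path = Path(path)
    _check_format(path)
    img = sitk.ReadImage(str(path))
    grid = _grid_from_image(img)
    occ = _array_from_image(img) != 0
    return StructureMask(grid, name or path.stem.split(".")[0], role, occ)


def write_dose(dose: DoseGrid, path: str | os.PathLike) -> None:
    path = Path(path)
    _check_format(path)
    img = _image_from_array(dose.dose_gy.astype(np.float64), dose.grid)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_dose(path: str | os.PathLike, phase_label: str = "phase1") -> DoseGrid:
    path = Path(path)
    _check_format(path)
    img = sitk.ReadImage(str(path))
    grid = _grid_from_image(img)
    return DoseGrid(grid, _array_from_image(img), phase_label)


# ---------------------------------------------------------------------------
# Structure-set manifest
# ---------------------------------------------------------------------------

@dataclass
class StructureSetManifest:
    """Index of one synthetic case: structure files, roles and prescription."""

    case_id: str
    entries: list[dict] = field(default_factory=list)  # {name, role, file}
    prescription: dict = field(default_factory=dict)
    grid: VoxelGrid | None = None

    def __post_init__(self):
        roles = [e["role"] for e in self.entries]
        for required in ("GTV", "Body"):
            if roles.count(required) != 1:
                raise ValueError(
                    f"manifest {self.case_id!r} must contain exactly one "
                    f"{required} entry, found {roles.count(required)}"
                )

    def entry_for(self, role: str) -> dict:
        matches = [e for e in self.entries if e["role"] == role]
        if not matches:
            raise KeyError(f"no entry with role {role!r} in case {self.case_id!r}")
        return matches[0]


def write_manifest(manifest: StructureSetManifest, path: str | os.PathLike) -> None:
    doc = {
        "case_id": manifest.case_id,
        "entries": manifest.entries,
        "prescription": manifest.prescription,
    }
    if manifest.grid is not None:
        doc["grid"] = {
            "origin_mm": list(manifest.grid.origin_mm),
            "spacing_mm": list(manifest.grid.spacing_mm),
            "dims": list(manifest.grid.dims),
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_manifest(path: str | os.PathLike) -> StructureSetManifest:
    doc = json.loads(Path(path).read_text())
    grid = None
    if "grid" in doc:
        g = doc["grid"]
        grid = VoxelGrid(tuple(g["origin_mm"]), tuple(g["spacing_mm"]), tuple(g["dims"]))
    return StructureSetManifest(
        case_id=doc["case_id"],
        entries=doc["entries"],
        prescription=doc.get("prescription", {}),
        grid=grid,
    )


def load_case_masks(manifest: StructureSetManifest,
                    base_dir: str | os.PathLike) -> dict[str, StructureMask]:
    """Load every mask referenced by a manifest, enforcing a common grid."""
    base = Path(base_dir)
    masks: dict[str, StructureMask] = {}
    ref_grid = None
    for entry in manifest.entries:
        m = read_mask(base / entry["file"], name=entry["name"], role=entry["role"])
        if ref_grid is None:
            ref_grid = m.grid
        elif not ref_grid.same_geometry(m.grid):
            raise GridMismatchError(
                f"mask {entry['name']!r} grid differs from the case grid"
            )
        masks[entry["name"]] = m
    return masks
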