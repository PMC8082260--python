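"""Reading and writing the formats the pipeline moves between.

Binary label masks travel as NIfTI-1 volumes, surface meshes as PLY, and
sparse contour sets as a small JSON schema
``{structure, axis, contours: [{plane_mm, points: [[x, y, z], ...]}]}``.

Conventions used throughout the package:

* masks are indexed with 0-based voxel indices and the third array axis is
  the axial (slice) axis;
* contours and meshes live in world millimetres, with voxel index ``i``
  mapping to world coordinate ``origin + i * spacing`` (voxel-*center*
  convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "read_mask",
    "write_mask",
    "read_contours",
    "write_contours",
    "read_mesh",
    "write_mesh",
]


@dataclass
class LabelMask:
    """A binary 3D voxel grid with world geometry.

    Parameters
    ----------
    data
        3D array of {0, 1} labels (stored as ``uint8``).
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World coordinate (mm) of the *center* of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got {self.data.ndim}D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, [0, 1])):
            warnings.warn(
                f"mask contains labels {sorted(int(v) for v in vals if v not in (0, 1))}; "
                "binarizing nonzero -> 1",
                stacklevel=2,
            )
        self.data = (self.data != 0).astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3 vectors")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self) -> float:
        """Volume of the foreground in millilitres (1 mL = 1000 mm^3)."""
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0

    def voxel_centers_world(self, axis: int | None = None) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis (or all)."""
        if axis is None:
            return np.stack(
                [self.voxel_centers_world(a) for a in range(3)], axis=0
            )
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_grid(self, other: "LabelMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy(self) -> "LabelMask":
        return LabelMask(self.data.copy(), self.spacing.copy(), self.origin.copy())


def _affine_from_geometry(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def read_mask(path: str | Path) -> LabelMask:
    """Read a NIfTI volume as a binary :class:`LabelMask`.

    Nonzero voxels map to 1 (with a warning if labels other than {0, 1}
    occur).  The volume is reoriented to the closest canonical (RAS)
    orientation so that the third array axis is axial.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = affine[:3, 3].astype(float)
    return LabelMask(data, spacing, origin)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a :class:`LabelMask` as NIfTI; lossless round-trip with read_mask."""
    path = Path(path)
    affine = _affine_from_geometry(mask.spacing, mask.origin)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Sparse contour sets (JSON)
# ---------------------------------------------------------------------------

_AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


def write_contours(contour_set, path: str | Path) -> Path:
    """Serialize a SparseContourSet to JSON (world-mm coordinates)."""
    path = Path(path)
    doc = {
        "structure": contour_set.structure,
        "axis": contour_set.axis_name,
        "contours": [
            {
                "plane_mm": float(c.plane),
                "points": np.asarray(c.points, dtype=float).tolist(),
            }
            for c in contour_set.contours
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_contours(path: str | Path):
    """Read a contour-set JSON file; contours come back sorted by plane."""
    from .contours import PlanarContour, SparseContourSet

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    axis_name = doc.get("axis", "z")
    if axis_name not in _AXIS_NAMES:
        raise ValueError(f"unknown slicing axis {axis_name!r}")
    raw = doc.get("contours", [])
    if not raw:
        raise ValueError(f"{path}: no contours")
    contours = []
    for entry in raw:
        pts = np.asarray(entry["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError(
                f"{path}: each contour needs >= 3 points of 3 coordinates"
            )
        contours.append(PlanarContour(float(entry["plane_mm"]), pts,
                                      axis=_AXIS_NAMES[axis_name]))
    planes = [c.plane for c in contours]
    if any(b <= a for a, b in zip(planes, planes[1:])):
        logger.warning("%s: plane positions not ascending; sorting", path)
        contours.sort(key=lambda c: c.plane)
    return SparseContourSet(
        contours=contours,
        axis=_AXIS_NAMES[axis_name],
        structure=doc.get("structure", ""),
    )


# ---------------------------------------------------------------------------
# Surface meshes (PLY)
# ---------------------------------------------------------------------------


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    """Write a triangular surface mesh to PLY (vertices in world mm)."""
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    mesh.export(str(path))
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Read a PLY mesh; errors on empty or non-triangular input."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mesh = trimesh.load(str(path), process=False, force="mesh")
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError(f"{path}: empty mesh")
    faces = np.asarray(mesh.faces)
    if faces.shape[1] != 3:
        raise ValueError(f"{path}: non-triangular faces")
    return mesh
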