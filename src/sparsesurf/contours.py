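"""From full segmentations to prepared sparse contour sets.

The reduced-workload input to the fairing reconstruction is a small number
of closed planar contours outlined at regular slice intervals.  This module
covers the synthetic route to such input: convert a binary mask to a surface
mesh (marching cubes), slice the mesh with evenly spaced planes, and prepare
the resulting contours — equal point counts by arc-length resampling,
consistent counter-clockwise orientation, and start points aligned across
contours so the tube built on top of them is not twisted.

Plane/mesh intersections are computed exactly on the triangles (segment
chaining), never by re-voxelization, to avoid a second discretization error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .mask_io import LabelMask

logger = logging.getLogger(__name__)

__all__ = [
    "PlanarContour",
    "SparseContourSet",
    "mask_to_mesh",
    "extract_sparse_contours",
    "resample_contour",
    "prepare_contour_set",
]

_AXIS_LETTERS = "xyz"


def _inplane_axes(axis: int) -> tuple[int, int]:
    """The two in-plane axes, ordered so +area = counter-clockwise along +axis."""
    return (axis + 1) % 3, (axis + 2) % 3


@dataclass
class PlanarContour:
    """A closed planar polyline in world mm.

    ``points`` is an (n, 3) array with the first point *not* repeated at the
    end (closure is implicit); all points share the ``plane`` coordinate
    along ``axis``.
    """

    plane: float
    points: np.ndarray
    axis: int = 2

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("contour points must be an (n, 3) array")
        if len(self.points) < 3:
            raise ValueError(f"contour needs >= 3 points, got {len(self.points)}")
        if not np.allclose(self.points[:, self.axis], self.plane, atol=1e-6):
            raise ValueError("contour points do not lie on the stated plane")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def inplane(self) -> np.ndarray:
        u, v = _inplane_axes(self.axis)
        return self.points[:, [u, v]]

    def signed_area(self) -> float:
        """Shoelace area; positive = counter-clockwise viewed along +axis."""
        q = self.inplane()
        x, y = q[:, 0], q[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_ccw(self) -> bool:
        return self.signed_area() > 0

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass
class SparseContourSet:
    """Ordered closed contours along one slicing axis."""

    contours: list[PlanarContour]
    axis: int = 2
    structure: str = ""
    points_per_contour: int | None = None

    def __post_init__(self) -> None:
        if len(self.contours) < 2:
            raise ValueError(f"need >= 2 contours, got {len(self.contours)}")
        planes = self.planes
        if np.any(np.diff(planes) <= 0):
            raise ValueError("plane positions must be strictly increasing")
        if any(c.axis != self.axis for c in self.contours):
            raise ValueError("contour axis inconsistent with set axis")

    @property
    def planes(self) -> np.ndarray:
        return np.array([c.plane for c in self.contours])

    @property
    def axis_name(self) -> str:
        return _AXIS_LETTERS[self.axis]

    @property
    def is_prepared(self) -> bool:
        counts = {c.n_points for c in self.contours}
        return len(counts) == 1 and all(c.is_ccw() for c in self.contours)


# ---------------------------------------------------------------------------
# Mask -> mesh
# ---------------------------------------------------------------------------


def mask_to_mesh(mask: LabelMask) -> trimesh.Trimesh:
    """Extract the 0.5 iso-surface of a binary mask as a watertight mesh.

    The mask is padded by one voxel so surfaces touching the array border
    still close; vertices are returned in world mm.
    """
    if mask.data.sum() == 0:
        raise ValueError("cannot mesh an empty mask")
    labels, n_comp = ndimage.label(mask.data, structure=np.ones((3, 3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        raise ValueError(
            f"mask has {n_comp} connected components (sizes {sizes.astype(int).tolist()}); "
            "mesh one structure at a time"
        )
    padded = np.pad(mask.data, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - mask.spacing + mask.origin  # undo the 1-voxel pad, to world mm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise RuntimeError("marching cubes produced a non-watertight mesh")
    return mesh


# ---------------------------------------------------------------------------
# Mesh -> sparse contours
# ---------------------------------------------------------------------------


def _loop_area(loop: np.ndarray, axis: int) -> float:
    u, v = _inplane_axes(axis)
    x, y = loop[:, u], loop[:, v]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_sparse_contours(
    mesh: trimesh.Trimesh,
    n_contours: int,
    axis: int = 2,
    end_margin_mm: float = 0.5,
) -> SparseContourSet:
    """Slice a mesh with ``n_contours`` evenly spaced planes along ``axis``.

    Plane positions run from ``min + end_margin_mm`` to ``max - end_margin_mm``
    inclusive (the default margin of half a 1 mm voxel keeps the planes just
    inside the surface).  If a plane cuts the mesh in several loops, the
    largest by enclosed area is kept with a warning.
    """
    if n_contours < 2:
        raise ValueError("need at least 2 contours")
    lo, hi = mesh.bounds[0][axis], mesh.bounds[1][axis]
    if hi - lo <= 2 * end_margin_mm:
        raise ValueError(
            f"mesh extent along axis {axis} ({hi - lo:.2f} mm) too small for "
            f"end margin {end_margin_mm} mm"
        )
    positions = np.linspace(lo + end_margin_mm, hi - end_margin_mm, n_contours)
    normal = np.zeros(3)
    normal[axis] = 1.0
    contours = []
    for z in positions:
        origin = normal * z
        section = mesh.section(plane_origin=origin, plane_normal=normal)
        loops = [] if section is None else [np.asarray(d) for d in section.discrete]
        loops = [lp[:-1] if np.allclose(lp[0], lp[-1]) else lp for lp in loops]
        loops = [lp for lp in loops if len(lp) >= 3]
        if not loops:
            raise ValueError(
                f"empty cross-section at plane {z:.2f} mm; the structure is "
                "narrower than the contour placement span — try fewer contours"
            )
        if len(loops) > 1:
            logger.warning(
                "plane %.2f mm cuts %d loops; keeping the largest by area", z, len(loops)
            )
        loop = max(loops, key=lambda lp: abs(_loop_area(lp, axis)))
        pts = loop.copy()
        pts[:, axis] = z  # snap the numerically sectioned points onto the plane
        contours.append(PlanarContour(float(z), pts, axis=axis))
    return SparseContourSet(contours=contours, axis=axis)


# ---------------------------------------------------------------------------
# Resampling and correspondence
# ---------------------------------------------------------------------------


def resample_contour(contour: PlanarContour, n_points: int) -> PlanarContour:
    """Resample a closed contour to ``n_points`` equal arc-length steps.

    The first output point coincides with the first input point; resampling
    an already-uniform contour to its own count is the identity.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    closed = np.vstack([contour.points, contour.points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate (zero-perimeter) contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = total * np.arange(n_points) / n_points
    new = np.column_stack(
        [np.interp(targets, s, closed[:, d]) for d in range(3)]
    )
    new[:, contour.axis] = contour.plane
    return PlanarContour(contour.plane, new, axis=contour.axis)


def _force_ccw(contour: PlanarContour) -> PlanarContour:
    if contour.is_ccw():
        return contour
    pts = contour.points
    rev = np.vstack([pts[:1], pts[:0:-1]])  # reverse order, keep start point
    return PlanarContour(contour.plane, rev, axis=contour.axis)


def _best_cyclic_shift(ref: np.ndarray, other: np.ndarray) -> int:
    """Shift minimizing sum of squared distances between corresponding points."""
    n = len(other)
    costs = np.empty(n)
    for s in range(n):
        costs[s] = np.sum((ref - np.roll(other, -s, axis=0)) ** 2)
    return int(np.argmin(costs))


def prepare_contour_set(cset: SparseContourSet, n_points: int = 64) -> SparseContourSet:
    """Resample, orient, and align a contour set for tube construction.

    All contours are resampled to ``n_points``, forced counter-clockwise
    (viewed along +axis), and the start point of each contour is cyclically
    shifted to minimize the sum of squared distances to its predecessor —
    exhaustive over all shifts, which is exact and cheap at n_points <= 256.
    Idempotent: a set already prepared at ``n_points`` is returned as-is
    (chord-based arc-length resampling is only asymptotically idempotent,
    so re-preparation is short-circuited by contract).
    """
    if cset.points_per_contour == n_points and cset.is_prepared:
        return cset
    prepared = [_force_ccw(resample_contour(c, n_points)) for c in cset.contours]
    aligned = [prepared[0]]
    for c in prepared[1:]:
        shift = _best_cyclic_shift(aligned[-1].points, c.points)
        pts = np.roll(c.points, -shift, axis=0)
        aligned.append(PlanarContour(c.plane, pts, axis=c.axis))
    return SparseContourSet(
        contours=aligned,
        axis=cset.axis,
        structure=cset.structure,
        points_per_contour=n_points,
    )
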