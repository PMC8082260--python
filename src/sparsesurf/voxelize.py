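"""Rasterize a closed surface mesh back onto a voxel grid.

A voxel is set iff its *center* lies inside the mesh, decided slice by
slice: the mesh is cut with the plane through each slice's voxel centers
(exact triangle/plane section), and grid points are tested against the
resulting loops with even-odd parity.  Planes are nudged by 1e-6 x spacing
before cutting so slices coinciding exactly with contour ring planes do not
produce degenerate coplanar cuts; the shift is far below discretization
error.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
import trimesh
from shapely.geometry import Polygon

from .mask_io import LabelMask

__all__ = ["voxelize_mesh", "volume_ml"]


def _slice_loops(mesh: trimesh.Trimesh, z: float, axis: int) -> list[np.ndarray]:
    normal = np.zeros(3)
    normal[axis] = 1.0
    section = mesh.section(plane_origin=normal * z, plane_normal=normal)
    if section is None:
        return []
    loops = []
    for d in section.discrete:
        d = np.asarray(d)
        if np.allclose(d[0], d[-1]):
            d = d[:-1]
        if len(d) >= 3:
            loops.append(d)
    return loops


def voxelize_mesh(mesh: trimesh.Trimesh, grid: LabelMask) -> LabelMask:
    """Scan-convert a watertight mesh to a binary mask on ``grid``'s geometry.

    ``grid`` supplies shape, spacing and origin only; its data is ignored.
    Raises if the mesh is not watertight or extends beyond the grid.
    """
    if not mesh.is_watertight:
        raise ValueError("voxelization requires a watertight mesh")
    lo = grid.origin - 0.5 * grid.spacing
    hi = grid.origin + (np.array(grid.shape) - 0.5) * grid.spacing
    if np.any(mesh.bounds[0] < lo - 1e-6) or np.any(mesh.bounds[1] > hi + 1e-6):
        raise ValueError(
            f"mesh bounds {mesh.bounds.tolist()} extend beyond the grid "
            f"[{lo.tolist()}, {hi.tolist()}]"
        )
    axis = 2
    u, v = 0, 1
    xs = grid.voxel_centers_world(u)
    ys = grid.voxel_centers_world(v)
    zs = grid.voxel_centers_world(axis)
    eps = 1e-6 * grid.spacing[axis]
    data = np.zeros(grid.shape, dtype=np.uint8)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    flat_x, flat_y = X.ravel(), Y.ravel()
    zmin, zmax = mesh.bounds[0][axis], mesh.bounds[1][axis]
    for k, z in enumerate(zs):
        if z < zmin or z > zmax:
            continue
        loops = _slice_loops(mesh, z + eps, axis)
        if not loops:
            continue
        parity = np.zeros(flat_x.shape, dtype=bool)
        for loop in loops:
            poly = Polygon(loop[:, [u, v]])
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.is_empty:
                continue
            parity ^= shapely.contains_xy(poly, flat_x, flat_y)
        data[:, :, k] = parity.reshape(len(xs), len(ys))
    if data.sum() == 0:
        warnings.warn(
            "voxelization produced an empty mask (mesh lies between voxel centers)",
            stacklevel=2,
        )
    return LabelMask(data, grid.spacing.copy(), grid.origin.copy())


def volume_ml(x: LabelMask | trimesh.Trimesh) -> float:
    """Volume in millilitres: voxel count for masks, divergence theorem for meshes."""
    if isinstance(x, LabelMask):
        return x.volume_ml()
    if isinstance(x, trimesh.Trimesh):
        if not x.is_watertight:
            raise ValueError("volume of a non-watertight mesh is undefined")
        return abs(float(x.volume)) / 1000.0
    raise TypeError(f"cannot compute a volume for {type(x).__name__}")
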