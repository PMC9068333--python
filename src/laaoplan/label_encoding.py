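"""Encode geometric landmarks as voxel label masks.

These encoders build the training-target representation used by the
landmark-detection networks: a point becomes a labelled sphere, a closed
curve becomes a torus-like tube (a sphere swept along the curve), and a
plane splits the blood-pool segmentation into two labelled regions.  Voxel
membership is decided by the voxel centre, matching the centroid-based
decoders.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Curve3D, Plane3D, Point3D
from .volume_io import LabelMask, VolumeGrid

__all__ = [
    "encode_point",
    "encode_curve",
    "encode_plane_split",
    "encode_segmentation",
    "DEFAULT_POINT_RADIUS_MM",
    "DEFAULT_CURVE_RADIUS_MM",
]

# Application-dependent label-region radii; exposed configuration, not claims.
DEFAULT_POINT_RADIUS_MM = 5.0
DEFAULT_CURVE_RADIUS_MM = 3.0


def _bounding_slices(grid: VolumeGrid, lo: np.ndarray, hi: np.ndarray):
    """Index slices covering the world box [lo, hi], clipped to the grid."""
    i_lo = np.floor(grid.world_to_index(lo)).astype(int)
    i_hi = np.ceil(grid.world_to_index(hi)).astype(int) + 1
    i_lo = np.clip(i_lo, 0, np.array(grid.shape))
    i_hi = np.clip(i_hi, 0, np.array(grid.shape))
    return tuple(slice(a, b) for a, b in zip(i_lo, i_hi))


def _voxel_centers(grid: VolumeGrid, slices) -> np.ndarray:
    axes = [grid.axis_coords(a)[s] for a, s in enumerate(slices)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def encode_point(p: Point3D, radius: float, grid: VolumeGrid) -> LabelMask:
    """Label the spherical region of ``radius`` mm around a point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = p.to_array() if isinstance(p, Point3D) else np.asarray(p, dtype=float)
    sl = _bounding_slices(grid, c - radius, c + radius)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if all(s.stop > s.start for s in sl):
        centers = _voxel_centers(grid, sl)
        inside = np.linalg.norm(centers - c, axis=1) <= radius
        shape = tuple(s.stop - s.start for s in sl)
        out[sl] = inside.reshape(shape).astype(np.uint8)
    if out.sum() == 0:
        raise ValueError("sphere does not cover any voxel centre of the grid")
    return LabelMask(out, grid.spacing.copy(), grid.origin.copy())


def _min_curvature_radius(vertices: np.ndarray, closed: bool) -> float:
    """Smallest circumradius over consecutive vertex triples."""
    v = vertices
    if closed:
        tri = zip(v, np.roll(v, -1, axis=0), np.roll(v, -2, axis=0))
    else:
        tri = zip(v[:-2], v[1:-1], v[2:])
    best = np.inf
    for a, b, c in tri:
        ab, bc, ca = np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c)
        cross = np.linalg.norm(np.cross(b - a, c - a))
        if cross > 1e-12:
            best = min(best, ab * bc * ca / (2 * cross))
    return best


def encode_curve(c: Curve3D, radius: float, grid: VolumeGrid) -> LabelMask:
    """Sweep a sphere of ``radius`` mm along the curve: a tubular label mask.

    A voxel is labelled iff its centre lies within ``radius`` of the
    polyline (exact point-to-segment distance).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if c.length() == 0:
        raise ValueError("degenerate curve: zero length")
    if c.n_vertices >= 3:
        rc = _min_curvature_radius(c.vertices, c.closed)
        if radius >= rc:
            warnings.warn(
                f"tube radius {radius:.2f} mm is not below the curve's minimum "
                f"radius of curvature {rc:.2f} mm; the swept tube self-intersects"
            )

    lo = c.vertices.min(axis=0) - radius
    hi = c.vertices.max(axis=0) + radius
    sl = _bounding_slices(grid, lo, hi)
    out = np.zeros(grid.shape, dtype=np.uint8)
    if not all(s.stop > s.start for s in sl):
        raise ValueError("curve tube does not intersect the grid")

    centers = _voxel_centers(grid, sl)
    step = float(min(grid.spacing)) / 2.0
    samples = c.densified(max_step=step)
    d_approx, _ = cKDTree(samples).query(centers, workers=-1)
    inside = d_approx <= radius - step
    uncertain = (~inside) & (d_approx <= radius + step)

    if np.any(uncertain):
        pts = centers[uncertain]
        a, b = c.segments()
        dmin = np.full(len(pts), np.inf)
        for p0, p1 in zip(a, b):
            d01 = p1 - p0
            denom = float(d01 @ d01)
            if denom == 0:
                dist = np.linalg.norm(pts - p0, axis=1)
            else:
                t = np.clip((pts - p0) @ d01 / denom, 0.0, 1.0)
                dist = np.linalg.norm(pts - (p0 + t[:, None] * d01), axis=1)
            np.minimum(dmin, dist, out=dmin)
        exact = np.zeros(len(centers), dtype=bool)
        exact[uncertain] = dmin <= radius
        inside |= exact

    shape = tuple(s.stop - s.start for s in sl)
    out[sl] = inside.reshape(shape).astype(np.uint8)
    if out.sum() == 0:
        raise ValueError("curve tube does not cover any voxel centre")
    return LabelMask(out, grid.spacing.copy(), grid.origin.copy())


def encode_plane_split(seg: LabelMask, plane: Plane3D, tip: Point3D | None = None) -> LabelMask:
    """Split a binary blood-pool mask into two labelled regions by a plane.

    Foreground voxels get label 1 or 2 by the sign of
    (voxel_centre - plane.point) . plane.normal.  By default label 2 is the
    positive-normal side; if ``tip`` (the appendage tip) is given, label 2
    is the side containing it, so label 2 is always the appendage side.
    """
    fg = seg.data > 0
    if not fg.any():
        raise ValueError("empty segmentation mask")
    axes = [seg.axis_coords(a) for a in range(3)]
    p0 = plane.point.to_array()
    n = plane.normal
    signed = (
        (axes[0] - p0[0])[:, None, None] * n[0]
        + (axes[1] - p0[1])[None, :, None] * n[1]
        + (axes[2] - p0[2])[None, None, :] * n[2]
    )
    positive_is_2 = True
    if tip is not None:
        tip_side = float(plane.signed_distance(tip.to_array()[None])[0])
        positive_is_2 = tip_side >= 0
    out = np.zeros(seg.shape, dtype=np.uint8)
    side2 = signed >= 0 if positive_is_2 else signed < 0
    out[fg & side2] = 2
    out[fg & ~side2] = 1
    if not ((out == 1).any() and (out == 2).any()):
        raise ValueError("plane does not intersect segmentation")
    return LabelMask(out, seg.spacing.copy(), seg.origin.copy())


def encode_segmentation(truth_mask: LabelMask, grid: VolumeGrid | None = None) -> LabelMask:
    """Pass through the ground-truth blood-pool mask, validating its grid."""
    if grid is not None and not truth_mask.same_geometry(grid):
        raise ValueError("segmentation truth is not defined on the target grid")
    if not (truth_mask.data > 0).any():
        raise ValueError("segmentation truth has no foreground voxels")
    return LabelMask(
        (truth_mask.data > 0).astype(np.uint8), truth_mask.spacing.copy(), truth_mask.origin.copy()
    )
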