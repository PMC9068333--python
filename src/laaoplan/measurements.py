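"""Clinical measurements: cross-section contours, diameters, and depths.

At each detected plane (anatomical ostium, device landing zones) the
appendage boundary is extracted as the closed intersection contour of the
blood-pool iso-surface with the plane, and four diameters are derived:

* area-based      2 * sqrt(A / pi)   — diameter of the equal-area circle
* perimeter-based P / pi             — diameter of the equal-perimeter circle
* maximum         largest caliper diameter of the contour
* minimum         smallest caliper width of the contour's convex hull

Two device-specific appendage depths are computed: the Amulet depth is the
distance from the ostium-contour centroid to the appendage roof along the
plane normal; the Watchman FLX depth is the distance from the landing-zone
centroid to the appendage tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.measure import marching_cubes

from .geometry import Curve3D, Plane3D, Point3D
from .volume_io import LabelMask

__all__ = [
    "Diameters",
    "CrossSection",
    "cross_section",
    "compute_diameters",
    "depth_amulet",
    "depth_watchman",
    "estimate_tip",
    "segmentation_surface",
]


@dataclass(frozen=True)
class Diameters:
    area_based: float
    perimeter_based: float
    minimum: float
    maximum: float

    def as_dict(self) -> dict:
        return {
            "area_based": self.area_based,
            "perimeter_based": self.perimeter_based,
            "minimum": self.minimum,
            "maximum": self.maximum,
        }


@dataclass
class CrossSection:
    """Closed appendage boundary at a plane, with its four diameters."""

    plane: Plane3D
    contour: Curve3D
    area: float
    perimeter: float
    diameters: Diameters
    centroid: Point3D
    candidates: list = field(default_factory=list)  # other closed contours in the plane

    def validate(self, tol: float = 1e-6) -> None:
        d = self.plane.signed_distance(self.contour.vertices)
        if np.abs(d).max() > tol:
            raise ValueError("contour is not coplanar with its plane")
        dd = self.diameters
        if not (dd.minimum <= dd.area_based + tol and dd.area_based <= dd.maximum + tol):
            raise ValueError("diameter ordering violated: expect min <= area-based <= max")
        if dd.area_based > dd.perimeter_based + tol:
            raise ValueError("isoperimetric inequality violated: area-based > perimeter-based")
        if abs(dd.area_based - 2 * np.sqrt(self.area / np.pi)) > 1e-9:
            raise ValueError("area-based diameter inconsistent with area")
        if abs(dd.perimeter_based - self.perimeter / np.pi) > 1e-9:
            raise ValueError("perimeter-based diameter inconsistent with perimeter")


def _caliper_width_and_diameter(hull_pts: np.ndarray) -> tuple[float, float]:
    """Rotating-calipers width and diameter of a convex polygon (2D points)."""
    n = len(hull_pts)
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
    diameter = float(np.sqrt(d2.max()))
    width = np.inf
    for i in range(n):
        e = hull_pts[(i + 1) % n] - hull_pts[i]
        ne = np.linalg.norm(e)
        if ne == 0:
            continue
        normal = np.array([-e[1], e[0]]) / ne
        proj = (hull_pts - hull_pts[i]) @ normal
        width = min(width, float(proj.max() - proj.min()))
    return width, diameter


def compute_diameters(contour: Curve3D, plane: Plane3D | None = None) -> Diameters:
    """Four standard diameters of a simple closed planar polygon."""
    if not contour.closed:
        raise ValueError("diameters require a closed contour")
    pts = contour.vertices
    if plane is None:
        centroid = pts.mean(axis=0)
        _, svals, vt = np.linalg.svd(pts - centroid)
        if svals[-1] > 1e-6 * max(svals[0], 1.0):
            raise ValueError("contour is not planar")
        plane = Plane3D(Point3D.from_array(centroid), vt[-1])
    pts2d = plane.to_2d(pts)

    poly = Polygon(pts2d)
    if not poly.is_valid:
        raise ValueError("self-intersecting contour")
    area = float(poly.area)
    perimeter = float(poly.exterior.length)

    hull = np.asarray(poly.convex_hull.exterior.coords)[:-1]
    width, diameter = _caliper_width_and_diameter(hull)
    return Diameters(
        area_based=2.0 * np.sqrt(area / np.pi),
        perimeter_based=perimeter / np.pi,
        minimum=width,
        maximum=diameter,
    )


def segmentation_surface(
    seg: LabelMask, smooth_sigma_vox: float = 1.0, upsample: int = 2
) -> trimesh.Trimesh:
    """Iso-surface (level 0.5) of a binary mask as a world-mm triangle mesh.

    The binary mask is linearly upsampled by ``upsample`` and Gaussian
    smoothed (``smooth_sigma_vox`` in original voxels) before meshing: the
    0.5 level of the smoothed indicator stays on the true boundary for
    locally flat surfaces, while upsampling plus smoothing removes the voxel
    staircase and its axis-aligned flattening, which would otherwise bias
    contour perimeters and caliper widths.
    """
    mask = (np.asarray(seg.data) > 0).astype(np.float32)
    if not mask.any():
        raise ValueError("empty segmentation")
    # only the mask's bounding box matters for its iso-surface
    bbox = ndimage.find_objects(mask.astype(np.uint8), max_label=1)[0]
    offset_vox = np.array([s.start for s in bbox])
    mask = mask[bbox]
    pad = max(1, int(np.ceil(3 * smooth_sigma_vox)))
    padded = np.pad(mask, pad)
    f = max(1, int(upsample))
    if f > 1:
        n_fine = [(n - 1) * f + 1 for n in padded.shape]
        coords = np.meshgrid(*[np.arange(m) / f for m in n_fine], indexing="ij")
        padded = ndimage.map_coordinates(padded, np.stack(coords), order=1, mode="nearest")
    if smooth_sigma_vox > 0:
        padded = ndimage.gaussian_filter(padded, sigma=smooth_sigma_vox * f)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(seg.spacing / f))
    verts = verts + (seg.origin + (offset_vox - pad) * seg.spacing)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def cross_section(
    seg: LabelMask,
    plane: Plane3D,
    mesh: trimesh.Trimesh | None = None,
) -> CrossSection:
    """Closed boundary contour of the blood pool in a plane, with diameters.

    The iso-surface of the mask is intersected with the plane; among the
    resulting closed polygons, the one whose centroid lies nearest the
    plane's point is taken as the appendage boundary (other candidates are
    retained for audit).  A precomputed ``mesh`` from
    :func:`segmentation_surface` may be passed to amortise meshing across
    several planes.
    """
    if mesh is None:
        mesh = segmentation_surface(seg)
    section = mesh.section(plane_origin=plane.point.to_array(), plane_normal=plane.normal)
    if section is None:
        raise ValueError("plane does not intersect the segmentation surface")

    closed_contours = []
    any_open = False
    for pts in section.discrete:
        pts = np.asarray(pts, dtype=float)
        if len(pts) >= 4 and np.allclose(pts[0], pts[-1], atol=1e-9):
            closed_contours.append(Curve3D(plane.project(pts[:-1]), closed=True))
        else:
            any_open = True
    if not closed_contours:
        if any_open:
            raise ValueError("intersection contour is open (mask touches the grid boundary)")
        raise ValueError("plane does not intersect the segmentation surface")

    ref = plane.point.to_array()
    dists = [np.linalg.norm(c.centroid().to_array() - ref) for c in closed_contours]
    order = np.argsort(dists)
    contour = closed_contours[order[0]]
    others = [closed_contours[i] for i in order[1:]]

    pts2d = plane.to_2d(contour.vertices)
    poly = Polygon(pts2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
    area = float(poly.area)
    perimeter = float(contour.length())
    diam = compute_diameters(contour, plane)
    # keep the printed diameters internally consistent with area/perimeter
    diam = Diameters(
        area_based=2.0 * np.sqrt(area / np.pi),
        perimeter_based=perimeter / np.pi,
        minimum=diam.minimum,
        maximum=diam.maximum,
    )
    return CrossSection(
        plane=plane,
        contour=contour,
        area=area,
        perimeter=perimeter,
        diameters=diam,
        centroid=contour.centroid(),
        candidates=others,
    )


def _sample_inside(seg: LabelMask, pts: np.ndarray) -> np.ndarray:
    """Trilinear occupancy of world points in a binary mask (0..1)."""
    idx = seg.world_to_index(pts).T
    return ndimage.map_coordinates(
        (np.asarray(seg.data) > 0).astype(np.float32), idx, order=1, mode="constant", cval=0.0
    )


def depth_amulet(
    seg: LabelMask, ostium: Plane3D, *, mesh: trimesh.Trimesh | None = None
) -> float:
    """Appendage depth for Amulet sizing.

    Distance from the ostium cross-section centroid to its projection on the
    appendage surface ("roof"): the first exit of a ray cast from the
    centroid along the plane normal (which points into the appendage).  The
    exit is located on the same smoothed iso-surface used for the
    cross-sections, so depth and diameters share one surface estimate.
    """
    if mesh is None:
        mesh = segmentation_surface(seg)
    cs = cross_section(seg, ostium, mesh=mesh)
    start = cs.centroid.to_array()
    direction = ostium.normal

    # the normal must point into the appendage; flip if it immediately exits
    probe = start + np.outer(np.array([1.0, 2.0]) * max(seg.spacing), direction)
    if _sample_inside(seg, probe).max() < 0.5:
        direction = -direction

    ts = _ray_mesh_hits(mesh, start, direction)
    ts = ts[ts > 1e-6]
    if ts.size == 0:
        raise ValueError("ray never exits the segmentation within the grid")
    return float(ts.min())


def _ray_mesh_hits(mesh: trimesh.Trimesh, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Ray parameters t of all triangle intersections (Moller-Trumbore)."""
    tri = mesh.triangles
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction[None, :], e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin[None, :] - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
    return t[hit]


def _geodesic_distances(fg: np.ndarray, spacing: np.ndarray, start: int) -> np.ndarray:
    """Single-source intramask geodesic distances on a 5x5x5 chord stencil.

    The wide stencil keeps the metrication error of discrete shortest paths
    below ~1% (a 26-neighbour walk overestimates oblique distances by up to
    ~3%, enough to misplace the farthest point on a blunt cap).  Chords are
    only admitted when their midpoint is inside the mask.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    idx = np.argwhere(fg)
    n = len(idx)
    node_id = -np.ones(fg.shape, dtype=np.int64)
    node_id[tuple(idx.T)] = np.arange(n)

    offsets = []
    for raw in np.ndindex(5, 5, 5):
        d = (raw[0] - 2, raw[1] - 2, raw[2] - 2)
        # half-space of directions, primitive chords only
        if d > (0, 0, 0) and np.gcd.reduce([abs(c) for c in d]) == 1:
            offsets.append(np.array(d))
    rows, cols, weights = [], [], []
    shape = np.array(fg.shape)
    for d in offsets:
        lo = np.maximum(0, -d)
        hi = shape - np.maximum(0, d)
        ok = np.all(idx >= lo, axis=1) & np.all(idx < hi, axis=1)
        src = idx[ok]
        dst = src + d
        j = node_id[tuple(dst.T)]
        keep = j >= 0
        if np.any(np.abs(d) > 1):
            mid = src[keep] + np.rint(d / 2.0).astype(int)
            keep_idx = np.where(keep)[0][fg[tuple(mid.T)]]
            keep = np.zeros(len(src), dtype=bool)
            keep[keep_idx] = True
        i = node_id[tuple(src[keep].T)]
        j = node_id[tuple((src[keep] + d).T)]
        w = float(np.linalg.norm(d * spacing))
        rows.append(i)
        cols.append(j)
        weights.append(np.full(len(i), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    graph = coo_matrix(
        (np.concatenate([weights, weights]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=start)
    out = np.full(fg.shape, np.inf)
    out[tuple(idx.T)] = dist
    return out


def estimate_tip(seg: LabelMask, ostium: Plane3D) -> Point3D:
    """Appendage tip: the intramask-geodesically farthest foreground voxel
    from the ostium centroid, restricted to the appendage side of the plane.
    """
    fg_full = np.asarray(seg.data) > 0
    if not fg_full.any():
        raise ValueError("empty segmentation")
    # geodesics are only needed on the appendage side of the ostium plane
    axes = [seg.axis_coords(a) for a in range(3)]
    p0, nrm = ostium.point.to_array(), ostium.normal
    signed = (
        (axes[0] - p0[0])[:, None, None] * nrm[0]
        + (axes[1] - p0[1])[None, :, None] * nrm[1]
        + (axes[2] - p0[2])[None, None, :] * nrm[2]
    )
    fg_full = fg_full & (signed > -2.0 * float(max(seg.spacing)))  # keep a small apron
    if not fg_full.any():
        raise ValueError("no appendage-side voxels beyond the ostium plane")
    bbox = ndimage.find_objects(fg_full.astype(np.uint8), max_label=1)[0]
    offset = np.array([s.start for s in bbox])
    fg = fg_full[bbox]
    origin = seg.origin + offset * seg.spacing

    idx = np.argwhere(fg)
    start_idx = np.rint((ostium.point.to_array() - origin) / seg.spacing).astype(int)
    start_idx = np.clip(start_idx, 0, np.array(fg.shape) - 1)
    if not fg[tuple(start_idx)]:
        start_idx = idx[np.argmin(((idx - start_idx) ** 2).sum(axis=1))]
    node_id = np.flatnonzero(
        (idx == np.asarray(start_idx)).all(axis=1)
    )
    cum = _geodesic_distances(fg, seg.spacing, int(node_id[0]))

    world = origin + idx * seg.spacing
    side = ostium.signed_distance(world) > 0
    reach = cum[tuple(idx.T)]
    ok = side & np.isfinite(reach)
    if not ok.any():
        raise ValueError("no reachable appendage-side voxels beyond the ostium plane")
    return Point3D.from_array(world[ok][np.argmax(reach[ok])])


def depth_watchman(
    seg: LabelMask,
    landing: Plane3D,
    tip: Point3D | None = None,
    *,
    ostium: Plane3D | None = None,
) -> float:
    """Appendage depth for Watchman FLX sizing.

    Euclidean distance between the landing-zone cross-section centroid and
    the appendage tip.  When ``tip`` is not supplied it is estimated as the
    geodesically farthest point inside the mask beyond the ostium plane
    (``ostium`` then required).
    """
    cs = cross_section(seg, landing)
    if tip is None:
        if ostium is None:
            raise ValueError("either tip or the ostium plane must be supplied")
        tip = estimate_tip(seg, ostium)
    return cs.centroid.distance_to(tip)
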