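"""Geometric landmark primitives: points, closed 3D curves, and planes.

All coordinates are world millimetres in a right-handed, axis-aligned
coordinate system.  These are the objects the label decoders produce and
the measurement stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Point3D", "Curve3D", "Plane3D"]


@dataclass(frozen=True)
class Point3D:
    """A single landmark location in world millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Point3D coordinates must be finite")

    @classmethod
    def from_array(cls, a) -> "Point3D":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Point3D") -> float:
        return float(np.linalg.norm(self.to_array() - other.to_array()))


@dataclass
class Curve3D:
    """A polyline in world millimetres, optionally closed.

    Closed curves (mitral annulus, fossa ovalis, cross-section contours)
    do not repeat the first vertex; the closing segment is implicit.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("Curve3D vertices must be an (N, 3) array")
        if self.closed and len(self.vertices) < 3:
            raise ValueError("a closed curve needs at least 3 vertices")
        if len(self.vertices) >= 2:
            seglen = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
            if np.any(seglen == 0):
                # drop exact duplicates rather than reject
                keep = np.concatenate([[True], seglen > 0])
                self.vertices = self.vertices[keep]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment start/end vertex arrays, including the closing segment."""
        v = self.vertices
        if self.closed:
            return v, np.roll(v, -1, axis=0)
        return v[:-1], v[1:]

    def length(self) -> float:
        a, b = self.segments()
        return float(np.linalg.norm(b - a, axis=1).sum())

    def centroid(self) -> Point3D:
        """Arclength-weighted centroid (independent of vertex density)."""
        a, b = self.segments()
        w = np.linalg.norm(b - a, axis=1)
        if w.sum() == 0:
            raise ValueError("degenerate curve: zero length")
        mid = 0.5 * (a + b)
        return Point3D.from_array((mid * w[:, None]).sum(axis=0) / w.sum())

    def densified(self, max_step: float = 0.5) -> np.ndarray:
        """Resample the polyline so no segment exceeds ``max_step`` mm.

        Returns the point cloud (original vertices are retained).
        """
        a, b = self.segments()
        pts = []
        for p, q in zip(a, b):
            d = np.linalg.norm(q - p)
            n = max(1, int(np.ceil(d / max_step)))
            t = np.arange(n) / n
            pts.append(p + t[:, None] * (q - p))
        pts = np.concatenate(pts, axis=0)
        if not self.closed:
            pts = np.concatenate([pts, self.vertices[-1:]], axis=0)
        return pts

    def translated(self, delta) -> "Curve3D":
        return Curve3D(self.vertices + np.asarray(delta, dtype=float), self.closed)

    def perimeter_based_diameter(self) -> float:
        """Diameter of the circle with this closed curve's perimeter, P/pi."""
        if not self.closed:
            raise ValueError("perimeter-based diameter requires a closed curve")
        return self.length() / np.pi


@dataclass
class Plane3D:
    """An oriented plane given by a point on it and a unit normal."""

    point: Point3D
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if not isinstance(self.point, Point3D):
            self.point = Point3D.from_array(self.point)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.all(np.isfinite(n)):
            raise ValueError("plane normal must be a nonzero finite vector")
        self.normal = n / norm

    def signed_distance(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - self.point.to_array()) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions completing a right-handed frame."""
        n = self.normal
        helper = np.eye(3)[int(np.argmin(np.abs(n)))]
        u = np.cross(n, helper)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def project(self, pts) -> np.ndarray:
        """Orthogonal projection of world points onto the plane."""
        pts = np.asarray(pts, dtype=float)
        d = self.signed_distance(pts)
        return pts - np.outer(d, self.normal)

    def to_2d(self, pts) -> np.ndarray:
        """In-plane coordinates of world points with respect to ``basis()``."""
        u, v = self.basis()
        rel = np.asarray(pts, dtype=float) - self.point.to_array()
        return np.stack([rel @ u, rel @ v], axis=-1)

    def from_2d(self, pts2d) -> np.ndarray:
        u, v = self.basis()
        pts2d = np.asarray(pts2d, dtype=float)
        return self.point.to_array() + np.outer(pts2d[..., 0], u) + np.outer(pts2d[..., 1], v)

    def flipped(self) -> "Plane3D":
        return Plane3D(self.point, -self.normal)
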