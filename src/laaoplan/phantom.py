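"""Synthetic contrast-CT phantoms of a left atrium with appendage.

The phantom stands in for patient scans: a bright ellipsoidal chamber (the
contrast-filled left atrium) with an attached tubular appendage swept along
a curved, linearly tapering centreline.  Because the geometry is analytic,
every landmark the pipeline must recover is known exactly: the anatomical
ostium and device landing-zone planes (normal cross-sections of the tube on
its straight proximal segment, hence circles of known radius), the mitral
annulus and fossa ovalis as planar ellipses, the mitral-valve centre, the
appendage tip, and the two appendage depths.

The tube is the union of spheres of radius r(s) centred on the centreline;
for a linear taper with slope m the normal cross-section at arclength s is
a circle of radius r(s) / sqrt(1 - m^2) (the envelope of a cone of spheres),
and that exact value is what the analytic section records carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import Curve3D, Plane3D, Point3D
from .measurements import Diameters
from .volume_io import LabelMask, VolumeGrid

__all__ = [
    "PhantomSpec",
    "AnalyticSection",
    "LandmarkTruth",
    "TruthPerturbation",
    "default_spec",
    "generate_phantom",
    "perturb_truth",
    "tube_mask",
    "DEVICES",
]

DEVICES = ("amulet", "watchman_flx")

_CENTERLINE_STEP = 0.25  # mm


@dataclass
class PhantomSpec:
    """Full parametric description of one phantom case.

    The centreline is a dense polyline (built by :func:`default_spec` as a
    straight proximal segment followed by a tangent-continuous circular
    arc) and ``radii`` gives the tube radius at each centreline vertex;
    the radius profile must be positive and non-increasing towards the tip.
    """

    grid_shape: tuple = (128, 128, 128)
    spacing: tuple = (1.0, 1.0, 1.0)
    atrium_center: tuple = (48.0, 64.0, 64.0)
    atrium_semi_axes: tuple = (26.0, 22.0, 20.0)
    centerline: np.ndarray = None
    radii: np.ndarray = None
    ostium_fraction: float = 0.4  # arclength fraction along the centreline
    landing_offsets: dict = field(
        default_factory=lambda: {"amulet": 6.0, "watchman_flx": 10.0}
    )
    annulus_center: tuple = (48.0, 64.0, 42.0)
    annulus_semi_axes: tuple = (15.0, 12.0)
    annulus_normal: tuple = (0.0, 0.2, 1.0)
    fossa_center: tuple = (48.0, 85.0, 64.0)
    fossa_semi_axes: tuple = (9.0, 7.0)
    fossa_normal: tuple = (0.0, 1.0, 0.2)
    pool_intensity: float = 400.0
    background_intensity: float = 50.0
    noise_sigma: float = 15.0
    blur_sigma_mm: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centerline is None:
            built = _build_centerline(np.asarray(self.atrium_center, dtype=float))
            self.centerline, self.radii, self.ostium_fraction = built
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.centerline) != len(self.radii):
            raise ValueError("centerline and radius profile lengths differ")
        if np.any(self.radii <= 0):
            raise ValueError("tube radius profile must be strictly positive")
        if np.any(np.diff(self.radii) > 1e-9):
            raise ValueError("tube radius profile must be non-increasing towards the tip")
        s = _arclength(self.centerline)
        s_ost = self.ostium_fraction * s[-1]
        for dev, off in self.landing_offsets.items():
            if off < 0 or s_ost + off >= s[-1]:
                raise ValueError(f"landing offset for {dev} falls beyond the centreline")


def _arclength(pts: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _build_centerline(
    atrium_center: np.ndarray,
    a_x: float = 26.0,
    straight_beyond: float = 22.0,
    bend_radius: float = 20.0,
    bend_angle_deg: float = 75.0,
    r_root: float = 12.0,
    r_tip: float = 4.0,
    ostium_beyond_mm: float = 4.0,
):
    """Straight segment along +x, then a tangent-continuous circular arc.

    Returns (dense polyline, radius profile, ostium arclength fraction).
    The measurement planes sit on the straight segment, where the normal
    tube cross-section is analytically a circle.
    """
    u = np.array([1.0, 0.0, 0.0])
    s_straight = a_x + straight_beyond
    n1 = max(2, int(np.ceil(s_straight / _CENTERLINE_STEP)))
    t1 = np.linspace(0.0, s_straight, n1)
    straight = atrium_center + t1[:, None] * u

    end = straight[-1]
    arc_center = end + bend_radius * np.array([0.0, 1.0, 0.0])
    phi_max = np.radians(bend_angle_deg)
    n2 = max(2, int(np.ceil(bend_radius * phi_max / _CENTERLINE_STEP)))
    phi = np.linspace(0.0, phi_max, n2)[1:]
    arc = (
        arc_center[None, :]
        - bend_radius * np.cos(phi)[:, None] * np.array([0.0, 1.0, 0.0])
        + bend_radius * np.sin(phi)[:, None] * np.array([1.0, 0.0, 0.0])
    )
    pts = np.concatenate([straight, arc], axis=0)
    s = _arclength(pts)
    radii = r_root + (r_tip - r_root) * s / s[-1]
    ostium_fraction = (a_x + ostium_beyond_mm) / s[-1]
    return pts, radii, ostium_fraction


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A mildly randomised phantom, the per-case variation of the battery.

    The battery grid is 0.75 mm isotropic (the sub-millimetre regime of
    contrast cardiac CT); anatomy sizes vary around typical adult values.
    """
    rng = np.random.default_rng(seed)
    semi = np.array([26.0, 22.0, 20.0]) * rng.uniform(0.92, 1.08, 3)
    center = np.array([46.0, 64.0, 64.0])
    pts, radii, frac = _build_centerline(
        center,
        a_x=semi[0],
        straight_beyond=float(rng.uniform(18.0, 22.0)),
        bend_radius=float(rng.uniform(16.0, 20.0)),
        bend_angle_deg=float(rng.uniform(60.0, 80.0)),
        r_root=float(rng.uniform(10.5, 13.0)),
        r_tip=float(rng.uniform(3.5, 4.5)),
    )
    annulus_center = center + np.array([0.0, 0.0, -0.9 * semi[2]])
    fossa_center = center + np.array([0.0, 0.95 * semi[1], 0.0])
    spec = PhantomSpec(
        grid_shape=(172, 172, 172),
        spacing=(0.75, 0.75, 0.75),
        atrium_center=tuple(center),
        atrium_semi_axes=tuple(semi),
        centerline=pts,
        radii=radii,
        ostium_fraction=frac,
        annulus_center=tuple(annulus_center),
        annulus_semi_axes=(float(rng.uniform(13.5, 16.5)), float(rng.uniform(10.5, 13.0))),
        fossa_center=tuple(fossa_center),
        fossa_semi_axes=(float(rng.uniform(8.0, 10.0)), float(rng.uniform(6.0, 8.0))),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


@dataclass(frozen=True)
class AnalyticSection:
    """Exact cross-section values at a truth plane (circular tube section)."""

    center: Point3D
    area: float
    perimeter: float
    diameters: Diameters


@dataclass
class LandmarkTruth:
    """The complete ground-truth geometry of one case."""

    laa_mask: LabelMask
    ostium_plane: Plane3D
    landing_planes: dict
    annulus_curve: Curve3D
    fossa_curve: Curve3D
    mv_center: Point3D
    laa_tip: Point3D
    sections: dict = field(default_factory=dict)  # plane name -> AnalyticSection
    depths: dict = field(default_factory=dict)  # device -> mm

    def all_planes(self) -> dict:
        return {"ostium": self.ostium_plane, **{f"landing_{d}": p for d, p in self.landing_planes.items()}}

    def validate(self) -> None:
        for name, plane in self.all_planes().items():
            idx = np.rint(self.laa_mask.world_to_index(plane.point.to_array())).astype(int)
            if not (np.all(idx >= 0) and np.all(idx < np.array(self.laa_mask.shape))):
                raise ValueError(f"{name} plane centroid outside the grid")
            if self.laa_mask.data[tuple(idx)] == 0:
                raise ValueError(f"{name} plane centroid outside the blood pool")
        for name, curve in (("annulus", self.annulus_curve), ("fossa", self.fossa_curve)):
            if not curve.closed:
                raise ValueError(f"{name} curve must be closed")


def _ellipse_curve(center, semi_axes, normal, n_vertices: int = 128) -> Curve3D:
    plane = Plane3D(Point3D.from_array(center), np.asarray(normal, dtype=float))
    u, v = plane.basis()
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = (
        np.asarray(center, dtype=float)
        + semi_axes[0] * np.cos(theta)[:, None] * u
        + semi_axes[1] * np.sin(theta)[:, None] * v
    )
    return Curve3D(pts, closed=True)


def _tube_inside(points: np.ndarray, centerline: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Membership of world points in the union-of-spheres tube."""
    rmax = float(radii.max())
    tree = cKDTree(points)
    inside = np.zeros(len(points), dtype=bool)
    for i in range(len(centerline)):
        hits = tree.query_ball_point(centerline[i], radii[i])
        if hits:
            inside[hits] = True
    del tree
    return inside


def _pool_mask(spec: PhantomSpec, grid: VolumeGrid) -> np.ndarray:
    c = np.asarray(spec.atrium_center, dtype=float)
    a = np.asarray(spec.atrium_semi_axes, dtype=float)
    axes = [grid.axis_coords(i) for i in range(3)]
    ell = (
        ((axes[0] - c[0]) / a[0])[:, None, None] ** 2
        + ((axes[1] - c[1]) / a[1])[None, :, None] ** 2
        + ((axes[2] - c[2]) / a[2])[None, None, :] ** 2
    ) <= 1.0

    # tube: only voxels inside the centreline bounding box (+ max radius) can hit
    rmax = float(spec.radii.max())
    lo = spec.centerline.min(axis=0) - rmax
    hi = spec.centerline.max(axis=0) + rmax
    i_lo = np.clip(np.floor(grid.world_to_index(lo)).astype(int), 0, np.array(grid.shape))
    i_hi = np.clip(np.ceil(grid.world_to_index(hi)).astype(int) + 1, 0, np.array(grid.shape))
    sl = tuple(slice(a_, b_) for a_, b_ in zip(i_lo, i_hi))
    sub_axes = [axes[i][sl[i]] for i in range(3)]
    mesh = np.meshgrid(*sub_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    tube = np.zeros(grid.shape, dtype=bool)
    tube[sl] = _tube_inside(pts, spec.centerline, spec.radii).reshape(
        tuple(s.stop - s.start for s in sl)
    )
    return ell | tube


def _analytic_section(spec: PhantomSpec, s_query: float) -> AnalyticSection:
    s = _arclength(spec.centerline)
    center = np.array(
        [np.interp(s_query, s, spec.centerline[:, k]) for k in range(3)]
    )
    r = float(np.interp(s_query, s, spec.radii))
    m = (spec.radii[0] - spec.radii[-1]) / s[-1]  # linear taper slope
    r_eff = r / np.sqrt(1.0 - m * m)
    d = 2.0 * r_eff
    return AnalyticSection(
        center=Point3D.from_array(center),
        area=np.pi * r_eff**2,
        perimeter=2.0 * np.pi * r_eff,
        diameters=Diameters(d, d, d, d),
    )


def _analytic_depth_amulet(spec: PhantomSpec, start: np.ndarray, direction: np.ndarray) -> float:
    """Exit distance of the ostium-normal ray through the analytic blood pool."""
    ts = np.arange(0.0, 90.0, 0.02)
    pts = start + ts[:, None] * direction
    c = np.asarray(spec.atrium_center, dtype=float)
    a = np.asarray(spec.atrium_semi_axes, dtype=float)
    in_ell = (((pts - c) / a) ** 2).sum(axis=1) <= 1.0
    in_tube = _tube_inside(pts, spec.centerline, spec.radii)
    inside = in_ell | in_tube
    out = np.where(~inside)[0]
    if out.size == 0 or out[0] == 0:
        raise ValueError("analytic depth ray failed to start inside / exit the pool")
    return float(ts[out[0] - 1] + 0.01)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, LandmarkTruth]:
    """Render the phantom volume and assemble its exact ground truth.

    Deterministic given ``spec.seed``.  The intensity image is the two-level
    blood-pool indicator, Gaussian-blurred (``blur_sigma_mm``) and corrupted
    with additive Gaussian noise (``noise_sigma``).
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    grid = VolumeGrid(np.zeros(spec.grid_shape, dtype=np.float32), spacing, np.zeros(3))

    # anatomy must fit with margin
    margin = 5.0
    extent_hi = (np.array(spec.grid_shape) - 1) * spacing
    a = np.asarray(spec.atrium_semi_axes, dtype=float)
    c = np.asarray(spec.atrium_center, dtype=float)
    tube_lo = (spec.centerline - spec.radii[:, None]).min(axis=0)
    tube_hi = (spec.centerline + spec.radii[:, None]).max(axis=0)
    lo = np.minimum(c - a, tube_lo)
    hi = np.maximum(c + a, tube_hi)
    if np.any(lo < margin) or np.any(hi > extent_hi - margin):
        raise ValueError("phantom anatomy exceeds the grid (5 mm margin required)")

    pool = _pool_mask(spec, grid)
    intensity = np.where(pool, spec.pool_intensity, spec.background_intensity).astype(np.float32)
    if spec.blur_sigma_mm > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma=spec.blur_sigma_mm / spacing)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, intensity.shape).astype(np.float32)
    volume = VolumeGrid(intensity.astype(np.float32), spacing.copy(), np.zeros(3))

    s = _arclength(spec.centerline)
    s_ost = spec.ostium_fraction * s[-1]
    tangent = np.array([1.0, 0.0, 0.0])  # planes sit on the straight +x segment

    sections = {"ostium": _analytic_section(spec, s_ost)}
    ostium_plane = Plane3D(sections["ostium"].center, tangent)
    landing_planes = {}
    for dev, off in spec.landing_offsets.items():
        sec = _analytic_section(spec, s_ost + off)
        sections[f"landing_{dev}"] = sec
        landing_planes[dev] = Plane3D(sec.center, tangent)

    laa_mask = LabelMask(pool.astype(np.uint8), spacing.copy(), np.zeros(3))

    # the LAA tip is the intramask-geodesically farthest blood-pool point
    # beyond the ostium; a bent appendage has no closed form for it, so the
    # truth value is evaluated numerically on the truth mask
    from .measurements import estimate_tip

    tip = estimate_tip(laa_mask, ostium_plane)
    depths = {
        "amulet": _analytic_depth_amulet(spec, sections["ostium"].center.to_array(), tangent),
        "watchman_flx": sections["landing_watchman_flx"].center.distance_to(tip)
        if "watchman_flx" in spec.landing_offsets
        else np.nan,
    }

    truth = LandmarkTruth(
        laa_mask=laa_mask,
        ostium_plane=ostium_plane,
        landing_planes=landing_planes,
        annulus_curve=_ellipse_curve(spec.annulus_center, spec.annulus_semi_axes, spec.annulus_normal),
        fossa_curve=_ellipse_curve(spec.fossa_center, spec.fossa_semi_axes, spec.fossa_normal),
        mv_center=Point3D.from_array(np.asarray(spec.annulus_center, dtype=float)),
        laa_tip=tip,
        sections=sections,
        depths=depths,
    )
    truth.validate()
    return volume, truth


# ---------------------------------------------------------------------------
# Perturbations (imperfect-prediction models for robustness testing)


@dataclass(frozen=True)
class TruthPerturbation:
    """Deterministic-seeded noise applied to ground-truth geometry."""

    plane_tilt_deg: float = 0.0
    translation_mm: float = 0.0
    curve_jitter_mm: float = 0.0
    mask_morph_voxels: int = 0  # > 0 dilate, < 0 erode

    def __post_init__(self):
        if self.plane_tilt_deg < 0 or self.translation_mm < 0 or self.curve_jitter_mm < 0:
            raise ValueError("noise magnitudes must be non-negative")


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tilt_plane(plane: Plane3D, tilt_deg: float, shift_mm: float, rng) -> Plane3D:
    n = plane.normal
    p = plane.point.to_array()
    if tilt_deg > 0:
        helper = _random_unit(rng)
        axis = np.cross(n, helper)
        while np.linalg.norm(axis) < 1e-6:
            axis = np.cross(n, _random_unit(rng))
        axis /= np.linalg.norm(axis)
        th = np.radians(tilt_deg)
        n = n * np.cos(th) + np.cross(axis, n) * np.sin(th)  # Rodrigues, axis orthogonal to n
    if shift_mm > 0:
        p = p + shift_mm * _random_unit(rng)
    return Plane3D(Point3D.from_array(p), n)


def perturb_truth(truth: LandmarkTruth, noise: TruthPerturbation, seed: int = 0) -> LandmarkTruth:
    """Return a copy of the truth with seeded geometric noise applied.

    Zero noise returns an identical copy.  Plane tilts and translations
    have exactly the requested magnitude in a random direction; curve
    vertices receive i.i.d. Gaussian jitter of the requested sigma; the
    mask boundary is dilated (positive) or eroded (negative) by the
    requested number of voxels.
    """
    rng = np.random.default_rng(seed)

    ostium = _tilt_plane(truth.ostium_plane, noise.plane_tilt_deg, noise.translation_mm, rng)
    landing = {
        dev: _tilt_plane(p, noise.plane_tilt_deg, noise.translation_mm, rng)
        for dev, p in truth.landing_planes.items()
    }

    def jitter_curve(c: Curve3D) -> Curve3D:
        if noise.curve_jitter_mm == 0:
            return Curve3D(c.vertices.copy(), c.closed)
        return Curve3D(c.vertices + rng.normal(0.0, noise.curve_jitter_mm, c.vertices.shape), c.closed)

    def jitter_point(p: Point3D) -> Point3D:
        if noise.translation_mm == 0:
            return p
        return Point3D.from_array(p.to_array() + noise.translation_mm * _random_unit(rng))

    mask_data = truth.laa_mask.data > 0
    if noise.mask_morph_voxels > 0:
        mask_data = ndimage.binary_dilation(mask_data, iterations=noise.mask_morph_voxels)
    elif noise.mask_morph_voxels < 0:
        mask_data = ndimage.binary_erosion(mask_data, iterations=-noise.mask_morph_voxels)

    return LandmarkTruth(
        laa_mask=LabelMask(
            mask_data.astype(np.uint8), truth.laa_mask.spacing.copy(), truth.laa_mask.origin.copy()
        ),
        ostium_plane=ostium,
        landing_planes=landing,
        annulus_curve=jitter_curve(truth.annulus_curve),
        fossa_curve=jitter_curve(truth.fossa_curve),
        mv_center=jitter_point(truth.mv_center),
        laa_tip=jitter_point(truth.laa_tip),
        sections=dict(truth.sections),
        depths=dict(truth.depths),
    )


# ---------------------------------------------------------------------------
# Simple analytic masks for calibration tests


def tube_mask(
    semi_axes: tuple = (10.0, 10.0),
    length: float = 60.0,
    spacing: float = 1.0,
    pad_mm: float = 6.0,
) -> tuple[LabelMask, Plane3D]:
    """An elliptic (or circular) cylinder mask along +z and its mid-plane.

    The analytic mid-plane cross-section is the ellipse with the given
    semi-axes; useful as a closed-form calibration target for the
    cross-section measurements.
    """
    a, b = semi_axes
    nx = int(round((2 * (a + pad_mm)) / spacing)) + 1
    ny = int(round((2 * (b + pad_mm)) / spacing)) + 1
    nz = int(round((length + 2 * pad_mm) / spacing)) + 1
    grid = VolumeGrid(np.zeros((nx, ny, nz), dtype=np.uint8), np.full(3, float(spacing)), np.zeros(3))
    cx, cy = (nx - 1) * spacing / 2.0, (ny - 1) * spacing / 2.0
    z0, z1 = pad_mm, pad_mm + length
    xs, ys, zs = (grid.axis_coords(i) for i in range(3))
    inside = (
        (((xs - cx) / a)[:, None, None] ** 2 + ((ys - cy) / b)[None, :, None] ** 2 <= 1.0)
        & ((zs >= z0) & (zs <= z1))[None, None, :]
    )
    mask = LabelMask(inside.astype(np.uint8), grid.spacing, grid.origin)
    mid = Plane3D(Point3D(cx, cy, (z0 + z1) / 2.0), np.array([0.0, 0.0, 1.0]))
    return mask, mid
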