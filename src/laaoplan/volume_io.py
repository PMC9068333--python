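"""Volumes on axis-aligned world grids: I/O and preprocessing.

A :class:`VolumeGrid` is a 3D scalar field (CT intensity, label or
probability values) with world geometry.  Voxel indices are 0-based, a
voxel's world position is its centre, and world(i) = origin + i * spacing.
Preprocessing (isotropic resampling, resizing, cropping) always preserves
the world frame, so landmarks decoded on a preprocessed grid are already
in the original world coordinates; the :class:`GridTransform` returned by
resize/crop records this mapping explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import Point3D

__all__ = [
    "VolumeGrid",
    "LabelMask",
    "ProbabilityMask",
    "GridTransform",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "resample_mask_to_grid",
    "resize_to_shape",
    "crop_around_point",
]


@dataclass
class VolumeGrid:
    """A 3D scalar field with axis-aligned world geometry (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: str = "xyz"  # data index order convention tag

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeGrid requires a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of the voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def contains_point(self, p) -> bool:
        idx = self.world_to_index(np.asarray(p, dtype=float))
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def same_geometry(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "VolumeGrid":
        return replace(self, data=self.data.copy(), spacing=self.spacing.copy(), origin=self.origin.copy())


class LabelMask(VolumeGrid):
    """A VolumeGrid whose voxel values are integer labels (0 = background)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label mask values must be integers")
            self.data = rounded.astype(np.int16)

    def label_set(self) -> np.ndarray:
        return np.unique(self.data)

    def foreground(self) -> np.ndarray:
        return self.data > 0


class ProbabilityMask(VolumeGrid):
    """A VolumeGrid of per-voxel probabilities for a single label."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=float)
        if self.data.size and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)


@dataclass(frozen=True)
class GridTransform:
    """World-to-world mapping between a source grid and a derived grid.

    Every preprocessing operation here preserves world coordinates, so the
    mapping is the identity; the object still carries both geometries so a
    pipeline can document and compose its preprocessing chain, and so a
    non-world-preserving transform could be slotted in later.
    """

    src_spacing: tuple
    src_origin: tuple
    dst_spacing: tuple
    dst_origin: tuple

    @classmethod
    def between(cls, src: VolumeGrid, dst: VolumeGrid) -> "GridTransform":
        return cls(tuple(src.spacing), tuple(src.origin), tuple(dst.spacing), tuple(dst.origin))

    def forward(self, pts) -> np.ndarray:
        """Map world points of the source frame into the derived frame."""
        return np.asarray(pts, dtype=float)

    def inverse(self, pts) -> np.ndarray:
        """Map world points of the derived frame back to the source frame."""
        return np.asarray(pts, dtype=float)

    @property
    def is_identity(self) -> bool:
        return True


# ---------------------------------------------------------------------------
# I/O


def _affine_from_grid(v: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(v.spacing)
    aff[:3, 3] = v.origin
    return aff


def write_volume(v: VolumeGrid, path) -> None:
    """Write a volume or mask as NIfTI with a diagonal affine."""
    img = nib.Nifti1Image(np.asanyarray(v.data), _affine_from_grid(v))
    nib.save(img, str(path))


def _read_nifti(path) -> VolumeGrid:
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    off_diagonal = rot - np.diag(np.diag(rot))
    if np.abs(off_diagonal).max() > 1e-4 * np.abs(np.diag(rot)).max():
        raise ValueError(
            f"{path}: oblique NIfTI orientation not supported; resample to an "
            "axis-aligned grid first"
        )
    data = np.asanyarray(img.dataobj)
    spacing = np.diag(rot).copy()
    origin = aff[:3, 3].copy()
    # normalise negative (flipped) axes to positive spacing
    for ax in range(3):
        if spacing[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
            spacing[ax] = -spacing[ax]
    return VolumeGrid(np.ascontiguousarray(data), spacing, origin)


def _read_dicom_series(path) -> VolumeGrid:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{path}: no readable DICOM slices")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    if not (np.allclose(row, [1, 0, 0], atol=1e-3) and np.allclose(col, [0, 1, 0], atol=1e-3)):
        raise ValueError(
            f"{path}: oblique DICOM orientation not supported; only axis-aligned "
            "series are read directly"
        )
    normal = np.cross(row, col)
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, dtype=float), iop, atol=1e-4):
            raise ValueError(f"{path}: inconsistent slice orientations")
    in_plane = np.asarray(slices[0].PixelSpacing, dtype=float)
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.PixelSpacing, dtype=float), in_plane, rtol=1e-3):
            raise ValueError(f"{path}: inconsistent in-plane spacing across slices")

    pos = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in slices])
    z = pos @ normal
    order = np.argsort(z)
    slices = [slices[i] for i in order]
    z = z[order]
    dz = np.diff(z)
    if len(dz) == 0:
        raise ValueError(f"{path}: a DICOM series needs at least two slices")
    ref = np.median(dz)
    bad = np.where(np.abs(dz - ref) > 0.01 * abs(ref))[0]
    if bad.size:
        gaps = ", ".join(
            f"between slice {i} (z={z[i]:.2f} mm) and slice {i + 1} (z={z[i + 1]:.2f} mm)"
            for i in bad
        )
        raise ValueError(f"{path}: inconsistent slice spacing (possible missing slices) {gaps}")

    arrays = []
    for ds in slices:
        a = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(a * slope + intercept)
    # pixel_array is (rows, cols) = (y, x); build (x, y, z)
    data = np.stack(arrays, axis=-1).transpose(1, 0, 2)
    spacing = np.array([in_plane[1], in_plane[0], abs(ref)])
    origin = pos[order][0]
    return VolumeGrid(np.ascontiguousarray(data), spacing, origin)


def read_volume(path, format: str | None = None) -> VolumeGrid:
    """Read a NIfTI file or an axis-aligned DICOM series directory."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p)
    if format == "dicom_series":
        return _read_dicom_series(p)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing


def _mask_like(v: VolumeGrid, data: np.ndarray, spacing, origin) -> VolumeGrid:
    if isinstance(v, LabelMask):
        return LabelMask(data, spacing, origin, v.axes)
    if isinstance(v, ProbabilityMask):
        return ProbabilityMask(data, spacing, origin, v.axes)
    return VolumeGrid(data, spacing, origin, v.axes)


def resample_isotropic(v: VolumeGrid, target_spacing: float, interpolation: str = "linear") -> VolumeGrid:
    """Resample to an isotropic voxel size, preserving the world extent.

    ``interpolation`` must be ``nearest`` for label masks so that labels
    never acquire interpolated fractional values.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if any(n == 0 for n in v.shape):
        raise ValueError("cannot resample a zero-extent volume")
    if isinstance(v, LabelMask) and interpolation != "nearest":
        raise ValueError("label masks must be resampled with nearest interpolation")
    order = {"linear": 1, "nearest": 0}[interpolation]

    t = float(target_spacing)
    new_shape = tuple(
        max(1, int(np.floor((n - 1) * s / t + 0.5)) + 1) for n, s in zip(v.shape, v.spacing)
    )
    coords = np.meshgrid(
        *[np.arange(m) * t / s for m, s in zip(new_shape, v.spacing)], indexing="ij"
    )
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=v.data.dtype if order == 0 else float),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    return _mask_like(v, out, np.full(3, t), v.origin.copy())


def resample_mask_to_grid(mask: LabelMask, grid: VolumeGrid) -> LabelMask:
    """Nearest-neighbour resample of a label mask onto another grid's geometry."""
    if mask.same_geometry(grid):
        return LabelMask(mask.data.copy(), grid.spacing.copy(), grid.origin.copy())
    idx = [(grid.axis_coords(ax) - mask.origin[ax]) / mask.spacing[ax] for ax in range(3)]
    mesh = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(mask.data, np.stack(mesh), order=0, mode="constant", cval=0)
    return LabelMask(out, grid.spacing.copy(), grid.origin.copy())


def resize_to_shape(v: VolumeGrid, shape) -> tuple[VolumeGrid, GridTransform]:
    """Resample onto ``shape`` voxels covering the same physical extent.

    The whole field of view is retained in a coarser (or finer) format;
    spacing rescales accordingly and the world frame is unchanged.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("target shape must be positive")
    old = np.array(v.shape, dtype=float)
    new = np.array(shape, dtype=float)
    new_spacing = v.spacing * old / new
    # voxel cells tile the same extent; centres shift by half the size change
    new_origin = v.origin - 0.5 * v.spacing + 0.5 * new_spacing
    coords = np.meshgrid(
        *[(np.arange(m) + 0.5) * o / m - 0.5 for m, o in zip(shape, old)], indexing="ij"
    )
    order = 0 if isinstance(v, LabelMask) else 1
    out = ndimage.map_coordinates(
        np.asarray(v.data, dtype=v.data.dtype if order == 0 else float),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    result = _mask_like(v, out, new_spacing, new_origin)
    return result, GridTransform.between(v, result)


def crop_around_point(
    v: VolumeGrid, center: Point3D, shape, pad_value: float = 0.0
) -> tuple[VolumeGrid, GridTransform]:
    """Extract a ``shape``-voxel region centred on a world point.

    No resizing: spacing is preserved and voxels outside the source volume
    are filled with ``pad_value``.  World coordinates of retained voxels do
    not change.
    """
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValueError("crop shape must be positive")
    if isinstance(center, Point3D):
        c = center.to_array()
    else:
        c = np.asarray(center, dtype=float).reshape(3)
    if not v.contains_point(c):
        warnings.warn("crop centre lies outside the volume; result may be fully padded")
    c_idx = np.rint(v.world_to_index(c)).astype(int)
    start = c_idx - np.array(shape) // 2

    out = np.full(shape, pad_value, dtype=float if not isinstance(v, LabelMask) else v.data.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.array(shape), np.array(v.shape))
    if np.all(src_hi > src_lo):
        dst_lo = src_lo - start
        dst_hi = src_hi - start
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = v.data[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    new_origin = v.origin + start * v.spacing
    result = _mask_like(v, out, v.spacing.copy(), new_origin)
    return result, GridTransform.between(v, result)
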