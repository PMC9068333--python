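"""Predictor contract standing in for the trained landmark-detection networks.

The real system runs one deep model per task (blood-pool segmentation,
mitral-valve centre, annulus/fossa curves, ostium/landing planes), each
consuming a preprocessed isotropic volume and returning a probability mask
(or a two-label mask for plane tasks).  Training those models needs a large
annotated cohort and GPUs, so this module pins the tensor-in/tensor-out
boundary instead and provides reference implementations driven by phantom
ground truth: a perfect oracle, and a perturbed oracle that emulates
imperfect predictions (soft boundaries, geometric jitter, false-positive
speckle).  A trained model can be dropped in behind the same interface.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from . import label_encoding as enc
from .phantom import LandmarkTruth, TruthPerturbation, perturb_truth
from .volume_io import (
    GridTransform,
    LabelMask,
    ProbabilityMask,
    VolumeGrid,
    resample_mask_to_grid,
)

__all__ = [
    "TASK_REGISTRY",
    "PredictionRequest",
    "Predictor",
    "OracleTruthPredictor",
    "PerturbedOraclePredictor",
    "OracleNoise",
    "make_oracle",
]

# task name -> task kind
TASK_REGISTRY = {
    "laa_seg": "segmentation",
    "mv_center": "point",
    "mitral_annulus": "curve",
    "fossa_ovalis": "curve",
    "ostium_plane": "plane",
    "landing_amulet": "plane",
    "landing_watchman_flx": "plane",
}


@dataclass
class PredictionRequest:
    """One inference call: a task name plus the preprocessed volume."""

    task: str
    volume: VolumeGrid
    transform: GridTransform | None = None

    def __post_init__(self) -> None:
        if self.task not in TASK_REGISTRY:
            raise ValueError(f"unknown task {self.task!r}; known: {sorted(TASK_REGISTRY)}")
        sp = self.volume.spacing
        if not np.allclose(sp, sp[0], atol=1e-9):
            raise ValueError("prediction requests require an isotropic volume")

    @property
    def kind(self) -> str:
        return TASK_REGISTRY[self.task]


@runtime_checkable
class Predictor(Protocol):
    """Anything that maps a PredictionRequest to a probability/label mask."""

    def predict(self, req: PredictionRequest) -> ProbabilityMask | LabelMask: ...


def _mask_on_grid(truth_mask: LabelMask, grid: VolumeGrid) -> LabelMask:
    """Truth blood-pool mask resampled (nearest) onto the request grid."""
    binary = LabelMask(
        (truth_mask.data > 0).astype(np.uint8), truth_mask.spacing.copy(), truth_mask.origin.copy()
    )
    return resample_mask_to_grid(binary, grid)


class OracleTruthPredictor:
    """Perfect predictor: re-encodes the case's ground truth on any grid."""

    name = "oracle"

    def __init__(
        self,
        truth: LandmarkTruth,
        point_radius: float = enc.DEFAULT_POINT_RADIUS_MM,
        curve_radius: float = enc.DEFAULT_CURVE_RADIUS_MM,
    ) -> None:
        self.truth = truth
        self.point_radius = point_radius
        self.curve_radius = curve_radius

    # hook so the perturbed subclass can swap in noisy geometry per task
    def _truth_for(self, task: str) -> LandmarkTruth:
        return self.truth

    def _encode(self, task: str, grid: VolumeGrid) -> LabelMask:
        truth = self._truth_for(task)
        if task == "laa_seg":
            return _mask_on_grid(truth.laa_mask, grid)
        if task == "mv_center":
            return enc.encode_point(truth.mv_center, self.point_radius, grid)
        if task == "mitral_annulus":
            return enc.encode_curve(truth.annulus_curve, self.curve_radius, grid)
        if task == "fossa_ovalis":
            return enc.encode_curve(truth.fossa_curve, self.curve_radius, grid)
        if task in ("ostium_plane", "landing_amulet", "landing_watchman_flx"):
            plane = (
                truth.ostium_plane
                if task == "ostium_plane"
                else truth.landing_planes[task.removeprefix("landing_")]
            )
            seg = _mask_on_grid(truth.laa_mask, grid)
            return enc.encode_plane_split(seg, plane, tip=truth.laa_tip)
        raise ValueError(f"unknown task {task!r}")

    def predict(self, req: PredictionRequest) -> ProbabilityMask | LabelMask:
        mask = self._encode(req.task, req.volume)
        if req.kind == "plane":
            return mask
        return ProbabilityMask(mask.data.astype(float), mask.spacing, mask.origin)


@dataclass(frozen=True)
class OracleNoise:
    """Noise model emulating imperfect network output."""

    blur_mm: float = 0.0  # Gaussian blur of the hard mask -> soft probabilities
    jitter_mm: float = 0.0  # geometric displacement of the encoded landmark
    speckle_rate: float = 0.0  # per-voxel false-positive probability
    plane_tilt_deg: float = 0.0  # angular error of plane predictions

    @property
    def is_zero(self) -> bool:
        return (
            self.blur_mm == 0
            and self.jitter_mm == 0
            and self.speckle_rate == 0
            and self.plane_tilt_deg == 0
        )


def _smooth_curve_jitter(curve, sigma_mm: float, rng) -> "Curve3D":
    """Displace curve vertices by a circularly smooth field of rms ``sigma_mm``."""
    from .geometry import Curve3D

    n = len(curve.vertices)
    raw = rng.normal(size=(n, 3))
    smooth = ndimage.gaussian_filter1d(raw, sigma=max(2.0, n / 16.0), axis=0, mode="wrap")
    rms = np.sqrt((smooth**2).sum(axis=1).mean())
    if rms > 0:
        smooth *= sigma_mm / rms
    return Curve3D(curve.vertices + smooth, curve.closed)


class PerturbedOraclePredictor(OracleTruthPredictor):
    """Oracle with seeded, per-task geometric and voxel noise."""

    name = "perturbed_oracle"

    def __init__(
        self,
        truth: LandmarkTruth,
        noise: OracleNoise,
        seed: int = 0,
        point_radius: float = enc.DEFAULT_POINT_RADIUS_MM,
        curve_radius: float = enc.DEFAULT_CURVE_RADIUS_MM,
    ) -> None:
        super().__init__(truth, point_radius, curve_radius)
        self.noise = noise
        self.seed = int(seed)

    def _task_seed(self, task: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(task.encode())) % (2**31 - 1)

    def _truth_for(self, task: str) -> LandmarkTruth:
        if self.noise.is_zero:
            return self.truth
        # curves get a smooth (low-frequency) displacement field rather than
        # i.i.d. vertex jitter: network errors displace the whole detected
        # band, they do not roughen it vertex-by-vertex
        pert = TruthPerturbation(
            plane_tilt_deg=self.noise.plane_tilt_deg,
            translation_mm=self.noise.jitter_mm,
            curve_jitter_mm=0.0,
            mask_morph_voxels=0,
        )
        noisy = perturb_truth(self.truth, pert, seed=self._task_seed(task))
        if self.noise.jitter_mm > 0:
            rng = np.random.default_rng(self._task_seed(task) + 2)
            noisy.annulus_curve = _smooth_curve_jitter(noisy.annulus_curve, self.noise.jitter_mm, rng)
            noisy.fossa_curve = _smooth_curve_jitter(noisy.fossa_curve, self.noise.jitter_mm, rng)
        return noisy

    def predict(self, req: PredictionRequest) -> ProbabilityMask | LabelMask:
        mask = self._encode(req.task, req.volume)
        if req.kind == "plane":
            return mask  # plane noise already applied geometrically
        data = mask.data.astype(float)
        if self.noise.blur_mm > 0:
            data = ndimage.gaussian_filter(data, sigma=self.noise.blur_mm / req.volume.spacing)
        if self.noise.speckle_rate > 0:
            rng = np.random.default_rng(self._task_seed(req.task) + 1)
            data = np.maximum(data, (rng.random(data.shape) < self.noise.speckle_rate))
        return ProbabilityMask(np.clip(data, 0.0, 1.0), mask.spacing, mask.origin)


def make_oracle(
    truth: LandmarkTruth,
    noise: OracleNoise | None = None,
    seed: int = 0,
    **radii,
) -> OracleTruthPredictor:
    """Build the reference predictor for a case (perturbed when noisy)."""
    if noise is None or noise.is_zero:
        return OracleTruthPredictor(truth, **radii)
    return PerturbedOraclePredictor(truth, noise, seed=seed, **radii)
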