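"""End-to-end case analysis: predict, decode, measure, report.

One case flows through: isotropic resampling; blood-pool segmentation
(binarize + refinement); mitral-valve centre detection (which defines the
annulus region of interest); annulus and fossa curve detection; ostium and
landing-zone plane detection; cross-sections, the four diameters per plane,
and the two device depths.  Independent stages keep running when one fails;
failures are recorded as structured warnings in the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .decoding import binarize, decode_curve, decode_plane, decode_point, refine_segmentation
from .geometry import Curve3D, Point3D
from .measurements import CrossSection, cross_section, depth_amulet, depth_watchman, estimate_tip, segmentation_surface
from .metrics import (
    ComparisonRecord,
    curve_centroid_distance,
    curve_diameter_difference,
    dice,
    hausdorff,
    plane_angle,
    point_distance,
    tabulate_comparison,
)
from .predictor import TASK_REGISTRY, PredictionRequest, Predictor
from .sidecar import curve_to_dict, plane_to_dict, point_to_dict
from .volume_io import (
    LabelMask,
    VolumeGrid,
    crop_around_point,
    resample_isotropic,
    resample_mask_to_grid,
)

__all__ = ["PipelineConfig", "MeasurementReport", "run_case", "run_batch", "evaluate_case", "BatchResult"]

ALL_TASKS = tuple(TASK_REGISTRY)


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of the full workflow.

    Isotropic spacings are per application kind (the networks each expect
    their own resolution); the annulus curve task runs on a crop around the
    detected mitral-valve centre.
    """

    seg_spacing_mm: float = 0.75
    plane_spacing_mm: float = 0.75
    point_spacing_mm: float = 0.75
    curve_spacing_mm: float = 0.75
    threshold: float = 0.5
    refine_mode: str = "largest_component"
    tasks: tuple = ALL_TASKS
    annulus_crop_shape: tuple = (96, 96, 96)  # voxels at curve spacing
    curve_smooth_window: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MeasurementReport:
    """The pipeline's clinical output for one case."""

    case_id: str
    laa_mask: LabelMask | None = None
    ostium_section: CrossSection | None = None
    landing_sections: dict = field(default_factory=dict)  # device -> CrossSection
    planes: dict = field(default_factory=dict)  # name -> Plane3D
    depth_amulet_mm: float | None = None
    depth_watchman_mm: float | None = None
    annulus_curve: Curve3D | None = None
    fossa_curve: Curve3D | None = None
    mv_center: Point3D | None = None
    laa_tip: Point3D | None = None
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def sections(self) -> dict:
        out = {}
        if self.ostium_section is not None:
            out["ostium"] = self.ostium_section
        for dev, sec in self.landing_sections.items():
            out[f"landing_{dev}"] = sec
        return out

    def to_dict(self) -> dict:
        def sec_dict(s: CrossSection | None):
            if s is None:
                return None
            return {
                "plane": plane_to_dict(s.plane),
                "centroid_mm": [s.centroid.x, s.centroid.y, s.centroid.z],
                "area_mm2": s.area,
                "perimeter_mm": s.perimeter,
                "diameters_mm": s.diameters.as_dict(),
                "contour": curve_to_dict(s.contour),
            }

        return {
            "schema": "laaoplan-report-v1",
            "case_id": self.case_id,
            "ostium_section": sec_dict(self.ostium_section),
            "landing_sections": {d: sec_dict(s) for d, s in self.landing_sections.items()},
            "depth_amulet_mm": self.depth_amulet_mm,
            "depth_watchman_mm": self.depth_watchman_mm,
            "annulus_curve": curve_to_dict(self.annulus_curve) if self.annulus_curve else None,
            "fossa_curve": curve_to_dict(self.fossa_curve) if self.fossa_curve else None,
            "mv_center": point_to_dict(self.mv_center) if self.mv_center else None,
            "laa_tip": point_to_dict(self.laa_tip) if self.laa_tip else None,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def summary_rows(self) -> list[dict]:
        """One row per measured plane, for the CSV report."""
        rows = []
        for name, sec in self.sections().items():
            d = sec.diameters
            rows.append(
                {
                    "case_id": self.case_id,
                    "plane": name,
                    "area_based_diameter_mm": d.area_based,
                    "perimeter_based_diameter_mm": d.perimeter_based,
                    "minimum_diameter_mm": d.minimum,
                    "maximum_diameter_mm": d.maximum,
                    "centroid_x_mm": sec.centroid.x,
                    "centroid_y_mm": sec.centroid.y,
                    "centroid_z_mm": sec.centroid.z,
                    "normal_x": sec.plane.normal[0],
                    "normal_y": sec.plane.normal[1],
                    "normal_z": sec.plane.normal[2],
                    "depth_amulet_mm": self.depth_amulet_mm if name == "ostium" else np.nan,
                    "depth_watchman_mm": self.depth_watchman_mm
                    if name == "landing_watchman_flx"
                    else np.nan,
                }
            )
        return rows


def _get_predictor(predictors, task: str) -> Predictor:
    if hasattr(predictors, "predict"):
        return predictors
    try:
        return predictors[task]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"no predictor registered for task {task!r}") from exc


def run_case(
    volume: VolumeGrid,
    predictors,
    config: PipelineConfig = PipelineConfig(),
    case_id: str = "case",
) -> MeasurementReport:
    """Run the complete automated analysis workflow for one volume.

    ``predictors`` is a single Predictor serving all tasks or a mapping
    task name -> Predictor.  A segmentation failure aborts the plane and
    measurement stages (they depend on the mask); curve and point stages
    proceed independently.
    """
    report = MeasurementReport(case_id=case_id)
    report.provenance = {
        "software": f"laaoplan {__version__}",
        "config": config.to_dict(),
        "predictors": {
            t: getattr(_get_predictor(predictors, t), "name", type(_get_predictor(predictors, t)).__name__)
            for t in config.tasks
        },
    }
    tasks = set(config.tasks)

    def fail(stage: str, exc: Exception) -> None:
        report.warnings.append({"stage": stage, "error": f"{type(exc).__name__}: {exc}"})

    _iso_cache: dict[float, VolumeGrid] = {}

    def iso(spacing: float) -> VolumeGrid:
        if spacing not in _iso_cache:
            _iso_cache[spacing] = resample_isotropic(volume, spacing, "linear")
        return _iso_cache[spacing]

    # --- segmentation -------------------------------------------------
    laa = None
    if "laa_seg" in tasks:
        try:
            iso_seg = iso(config.seg_spacing_mm)
            prob = _get_predictor(predictors, "laa_seg").predict(
                PredictionRequest("laa_seg", iso_seg)
            )
            raw = binarize(prob, config.threshold)
            laa = refine_segmentation(raw, intensity=iso_seg, mode=config.refine_mode)
            report.laa_mask = laa
        except Exception as exc:
            fail("laa_seg", exc)

    # --- point detection ----------------------------------------------
    iso_pt = None
    if "mv_center" in tasks:
        try:
            iso_pt = iso(config.point_spacing_mm)
            prob = _get_predictor(predictors, "mv_center").predict(
                PredictionRequest("mv_center", iso_pt)
            )
            report.mv_center = decode_point(prob, config.threshold)
        except Exception as exc:
            fail("mv_center", exc)

    # --- curve detection ------------------------------------------------
    iso_curve = None
    if {"mitral_annulus", "fossa_ovalis"} & tasks:
        iso_curve = iso(config.curve_spacing_mm)
    if "mitral_annulus" in tasks:
        try:
            annulus_input = iso_curve
            transform = None
            if report.mv_center is not None:
                annulus_input, transform = crop_around_point(
                    iso_curve,
                    report.mv_center,
                    config.annulus_crop_shape,
                    pad_value=float(np.min(iso_curve.data)),
                )
            prob = _get_predictor(predictors, "mitral_annulus").predict(
                PredictionRequest("mitral_annulus", annulus_input, transform)
            )
            curve = decode_curve(prob, config.threshold, config.curve_smooth_window)
            if transform is not None:
                curve = Curve3D(transform.inverse(curve.vertices), curve.closed)
            report.annulus_curve = curve
        except Exception as exc:
            fail("mitral_annulus", exc)
    if "fossa_ovalis" in tasks:
        try:
            prob = _get_predictor(predictors, "fossa_ovalis").predict(
                PredictionRequest("fossa_ovalis", iso_curve)
            )
            report.fossa_curve = decode_curve(prob, config.threshold, config.curve_smooth_window)
        except Exception as exc:
            fail("fossa_ovalis", exc)

    # --- plane detection + measurements ---------------------------------
    plane_tasks = {"ostium_plane": "ostium"} | {
        f"landing_{d}": f"landing_{d}" for d in ("amulet", "watchman_flx")
    }
    if laa is None:
        for t in plane_tasks:
            if t in tasks:
                report.warnings.append(
                    {"stage": t, "error": "skipped: segmentation unavailable"}
                )
        return report

    iso_plane = iso(config.plane_spacing_mm)
    for task in [t for t in plane_tasks if t in tasks]:
        try:
            pred = _get_predictor(predictors, task).predict(
                PredictionRequest(task, iso_plane)
            )
            report.planes[plane_tasks[task]] = decode_plane(pred)
        except Exception as exc:
            fail(task, exc)

    mesh = None
    try:
        mesh = segmentation_surface(laa)
    except Exception as exc:
        fail("surface", exc)

    if mesh is not None:
        for name, plane in report.planes.items():
            try:
                sec = cross_section(laa, plane, mesh=mesh)
                if name == "ostium":
                    report.ostium_section = sec
                else:
                    report.landing_sections[name.removeprefix("landing_")] = sec
            except Exception as exc:
                fail(f"section_{name}", exc)

    ostium = report.planes.get("ostium")
    if ostium is not None and report.ostium_section is not None:
        try:
            report.depth_amulet_mm = depth_amulet(laa, ostium, mesh=mesh)
        except Exception as exc:
            fail("depth_amulet", exc)
        try:
            report.laa_tip = estimate_tip(laa, ostium)
        except Exception as exc:
            fail("laa_tip", exc)
    if "watchman_flx" in report.landing_sections and report.laa_tip is not None:
        try:
            report.depth_watchman_mm = depth_watchman(
                laa, report.planes["landing_watchman_flx"], tip=report.laa_tip
            )
        except Exception as exc:
            fail("depth_watchman", exc)
    return report


# ---------------------------------------------------------------------------
# Evaluation against ground truth and batch runs


def evaluate_case(report: MeasurementReport, truth, pair: str = "model_vs_truth") -> list[ComparisonRecord]:
    """Compare one report with ground truth, one record per landmark metric.

    Distances and angles are unsigned; diameter and depth differences are
    signed, predicted minus truth.
    """
    rec = []
    cid = report.case_id

    def add(landmark, metric, value, units):
        rec.append(ComparisonRecord(cid, landmark, metric, float(value), units, pair))

    if report.laa_mask is not None:
        truth_on_grid = resample_mask_to_grid(truth.laa_mask, report.laa_mask)
        add("laa_seg", "dice", dice(report.laa_mask, truth_on_grid), "1")

    if report.mv_center is not None:
        add("mv_center", "distance", point_distance(report.mv_center, truth.mv_center), "mm")

    for name, curve, truth_curve in (
        ("mitral_annulus", report.annulus_curve, truth.annulus_curve),
        ("fossa_ovalis", report.fossa_curve, truth.fossa_curve),
    ):
        if curve is None:
            continue
        add(name, "hausdorff", hausdorff(curve, truth_curve), "mm")
        add(name, "centroid_distance", curve_centroid_distance(curve, truth_curve), "mm")
        if curve.closed:
            add(name, "diameter_difference", curve_diameter_difference(curve, truth_curve), "mm")

    truth_planes = truth.all_planes()
    for name, sec in report.sections().items():
        tp = truth_planes.get(name)
        ts = truth.sections.get(name)
        if tp is None or ts is None:
            continue
        add(name, "plane_angle", plane_angle(sec.plane, tp), "deg")
        add(name, "centroid_distance", sec.centroid.distance_to(ts.center), "mm")
        d = sec.diameters
        td = ts.diameters
        add(name, "area_based_diameter_difference", d.area_based - td.area_based, "mm")
        add(name, "perimeter_based_diameter_difference", d.perimeter_based - td.perimeter_based, "mm")
        add(name, "minimum_diameter_difference", d.minimum - td.minimum, "mm")
        add(name, "maximum_diameter_difference", d.maximum - td.maximum, "mm")

    if report.depth_amulet_mm is not None and "amulet" in truth.depths:
        add("depth_amulet", "difference", report.depth_amulet_mm - truth.depths["amulet"], "mm")
    if report.depth_watchman_mm is not None and "watchman_flx" in truth.depths:
        add(
            "depth_watchman",
            "difference",
            report.depth_watchman_mm - truth.depths["watchman_flx"],
            "mm",
        )
    return rec


@dataclass
class BatchResult:
    reports: list
    records: list
    summary: pd.DataFrame | None

    def reports_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.extend(r.summary_rows())
        return pd.DataFrame(rows)


def run_batch(cases, config: PipelineConfig = PipelineConfig()) -> BatchResult:
    """Analyse a list of cases; summarise against truth when provided.

    Each case is a tuple ``(case_id, volume, predictors, truth_or_None)``.
    Individual case failures are logged in that case's report warnings and
    the batch continues.
    """
    if not cases:
        raise ValueError("run_batch needs at least one case")
    reports, records = [], []
    for case_id, volume, predictors, truth in cases:
        try:
            report = run_case(volume, predictors, config, case_id=case_id)
        except Exception as exc:  # a hard failure still yields a stub report
            report = MeasurementReport(case_id=case_id, warnings=[{"stage": "case", "error": str(exc)}])
        reports.append(report)
        if truth is not None:
            try:
                records.extend(evaluate_case(report, truth))
            except Exception as exc:
                report.warnings.append({"stage": "evaluation", "error": str(exc)})
    summary = tabulate_comparison(records) if records else None
    return BatchResult(reports=reports, records=records, summary=summary)
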