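"""JSON sidecar serialization for landmarks, ground truth, and reports.

Planes are stored as point + unit normal, curves as ordered world-mm vertex
lists, points as xyz triples.  The blood-pool mask travels separately as a
NIfTI file referenced by relative path from the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Curve3D, Plane3D, Point3D

__all__ = [
    "point_to_dict",
    "point_from_dict",
    "curve_to_dict",
    "curve_from_dict",
    "plane_to_dict",
    "plane_from_dict",
    "save_truth",
    "load_truth",
]


def point_to_dict(p: Point3D) -> dict:
    return {"xyz_mm": [p.x, p.y, p.z]}


def point_from_dict(d: dict) -> Point3D:
    return Point3D.from_array(d["xyz_mm"])


def curve_to_dict(c: Curve3D) -> dict:
    return {"vertices_mm": np.asarray(c.vertices).tolist(), "closed": bool(c.closed)}


def curve_from_dict(d: dict) -> Curve3D:
    return Curve3D(np.asarray(d["vertices_mm"], dtype=float), closed=bool(d["closed"]))


def plane_to_dict(p: Plane3D) -> dict:
    return {"point_mm": [p.point.x, p.point.y, p.point.z], "normal": np.asarray(p.normal).tolist()}


def plane_from_dict(d: dict) -> Plane3D:
    return Plane3D(Point3D.from_array(d["point_mm"]), np.asarray(d["normal"], dtype=float))


def save_truth(truth, json_path, mask_path=None) -> None:
    """Write a LandmarkTruth sidecar; the mask goes to ``mask_path`` (NIfTI)."""
    from .volume_io import write_volume

    json_path = Path(json_path)
    if mask_path is None:
        mask_path = json_path.with_name(json_path.stem + "_mask.nii.gz")
    mask_path = Path(mask_path)
    write_volume(truth.laa_mask, mask_path)

    doc = {
        "schema": "laaoplan-truth-v1",
        "laa_mask_file": mask_path.name,
        "ostium_plane": plane_to_dict(truth.ostium_plane),
        "landing_planes": {d: plane_to_dict(p) for d, p in truth.landing_planes.items()},
        "annulus_curve": curve_to_dict(truth.annulus_curve),
        "fossa_curve": curve_to_dict(truth.fossa_curve),
        "mv_center": point_to_dict(truth.mv_center),
        "laa_tip": point_to_dict(truth.laa_tip),
        "analytic_sections": {
            name: {
                "center_mm": [s.center.x, s.center.y, s.center.z],
                "area_mm2": s.area,
                "perimeter_mm": s.perimeter,
                "diameters_mm": s.diameters.as_dict(),
            }
            for name, s in truth.sections.items()
        },
        "depths_mm": truth.depths,
    }
    json_path.write_text(json.dumps(doc, indent=2))


def load_truth(json_path):
    """Read a LandmarkTruth sidecar written by :func:`save_truth`."""
    from .measurements import Diameters
    from .phantom import AnalyticSection, LandmarkTruth
    from .volume_io import LabelMask, read_volume

    json_path = Path(json_path)
    doc = json.loads(json_path.read_text())
    if doc.get("schema") != "laaoplan-truth-v1":
        raise ValueError(f"{json_path}: not a laaoplan truth sidecar")
    mask_grid = read_volume(json_path.with_name(doc["laa_mask_file"]))
    mask = LabelMask(
        np.rint(np.asarray(mask_grid.data)).astype(np.uint8), mask_grid.spacing, mask_grid.origin
    )
    sections = {
        name: AnalyticSection(
            center=Point3D.from_array(s["center_mm"]),
            area=float(s["area_mm2"]),
            perimeter=float(s["perimeter_mm"]),
            diameters=Diameters(**s["diameters_mm"]),
        )
        for name, s in doc.get("analytic_sections", {}).items()
    }
    return LandmarkTruth(
        laa_mask=mask,
        ostium_plane=plane_from_dict(doc["ostium_plane"]),
        landing_planes={d: plane_from_dict(p) for d, p in doc["landing_planes"].items()},
        annulus_curve=curve_from_dict(doc["annulus_curve"]),
        fossa_curve=curve_from_dict(doc["fossa_curve"]),
        mv_center=point_from_dict(doc["mv_center"]),
        laa_tip=point_from_dict(doc["laa_tip"]),
        sections=sections,
        depths={k: float(v) for k, v in doc.get("depths_mm", {}).items()},
    )
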