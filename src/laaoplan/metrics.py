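"""Evaluation metrics for segmentations, points, curves, and planes.

Conventions: distances are in mm and unsigned; plane angles are in degrees
within [0, 90] (a plane equals its flipped-normal twin); diameter
differences are signed, predicted minus reference.  The tabulation helper
summarises per-landmark metrics as mean +/- sample standard deviation per
comparator pair, the layout used for observer-variability reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Curve3D, Plane3D, Point3D
from .volume_io import LabelMask

__all__ = [
    "dice",
    "point_distance",
    "hausdorff",
    "curve_centroid_distance",
    "curve_diameter_difference",
    "plane_angle",
    "plane_centroid_distance",
    "ComparisonRecord",
    "tabulate_comparison",
    "format_comparison_table",
]


def dice(a: LabelMask, b: LabelMask) -> float:
    """Sorensen-Dice overlap 2|A.B| / (|A|+|B|); two empty masks give 1."""
    if not a.same_geometry(b):
        raise ValueError("masks are on different grids")
    fa = np.asarray(a.data) > 0
    fb = np.asarray(b.data) > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((fa & fb).sum()) / denom


def point_distance(a: Point3D, b: Point3D) -> float:
    return a.distance_to(b)


def _as_points(x, densify_step: float) -> np.ndarray:
    if isinstance(x, Curve3D):
        return x.densified(max_step=densify_step)
    pts = np.asarray(x, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("expected a non-empty (N, 3) point set or Curve3D")
    return pts


def hausdorff(a, b, densify_step: float = 0.5) -> float:
    """Symmetric Hausdorff distance between curves or point sets (mm).

    Curves are densified to at most ``densify_step`` mm vertex spacing first
    so vertex density does not bias the metric.
    """
    pa = _as_points(a, densify_step)
    pb = _as_points(b, densify_step)
    d_ab, _ = cKDTree(pb).query(pa, workers=-1)
    d_ba, _ = cKDTree(pa).query(pb, workers=-1)
    return float(max(d_ab.max(), d_ba.max()))


def curve_centroid_distance(a: Curve3D, b: Curve3D) -> float:
    """Euclidean distance between arclength-weighted curve centroids (mm)."""
    return a.centroid().distance_to(b.centroid())


def curve_diameter_difference(a: Curve3D, b: Curve3D) -> float:
    """Signed perimeter-based diameter difference, predicted minus truth (mm)."""
    return a.perimeter_based_diameter() - b.perimeter_based_diameter()


def plane_angle(a: Plane3D, b: Plane3D) -> float:
    """Unsigned angle between two planes in degrees, in [0, 90]."""
    c = abs(float(np.dot(a.normal, b.normal)))
    if c >= 1.0 - 1e-12:  # numerically identical normals
        return 0.0
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def plane_centroid_distance(a, b) -> float:
    """Distance between the centroids of the boundary contours in two planes.

    Accepts CrossSection objects (uses their contour centroids) or anything
    with a ``centroid`` Point3D attribute.
    """
    ca = a.centroid if isinstance(a.centroid, Point3D) else a.centroid()
    cb = b.centroid if isinstance(b.centroid, Point3D) else b.centroid()
    return ca.distance_to(cb)


@dataclass(frozen=True)
class ComparisonRecord:
    """One metric value for one landmark of one case under one comparison."""

    case_id: str
    landmark: str
    metric: str
    value: float
    units: str
    pair: str  # e.g. "model_vs_truth", "obs2_vs_obs1"

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("metric value must be finite")


def tabulate_comparison(records, pairs=None) -> pd.DataFrame:
    """Summarise comparison records as mean +/- sd per landmark/metric/pair.

    Returns a tidy DataFrame with columns (landmark, metric, units, pair,
    mean, sd, n); the sd is the sample (n-1) standard deviation and is NaN
    for singleton cells.  Requested pairs with no records appear with n=0
    rather than being dropped silently.
    """
    rows = [
        {
            "case_id": r.case_id,
            "landmark": r.landmark,
            "metric": r.metric,
            "units": r.units,
            "pair": r.pair,
            "value": r.value,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["case_id", "landmark", "metric", "units", "pair", "value"])
    if pairs is None:
        pairs = list(df["pair"].unique()) if len(df) else []

    if len(df):
        grouped = (
            df.groupby(["landmark", "metric", "units", "pair"], sort=False)["value"]
            .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index()
        )
    else:
        grouped = pd.DataFrame(columns=["landmark", "metric", "units", "pair", "mean", "sd", "n"])

    # surface empty requested cells explicitly
    cells = grouped[["landmark", "metric", "units"]].drop_duplicates()
    missing = []
    for _, cell in cells.iterrows():
        for pair in pairs:
            sel = (
                (grouped["landmark"] == cell["landmark"])
                & (grouped["metric"] == cell["metric"])
                & (grouped["pair"] == pair)
            )
            if not sel.any():
                missing.append({**cell.to_dict(), "pair": pair, "mean": np.nan, "sd": np.nan, "n": 0})
    if missing:
        grouped = pd.concat([grouped, pd.DataFrame(missing)], ignore_index=True)
    return grouped


def format_comparison_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tabulate_comparison summary to a printable mean +/- sd table."""

    def fmt(row):
        if row["n"] == 0 or not np.isfinite(row["mean"]):
            return "n/a"
        if not np.isfinite(row["sd"]):
            return f"{row['mean']:.1f} ± n/a"
        return f"{row['mean']:.1f} ± {row['sd']:.1f}"

    s = summary.copy()
    s["cell"] = s.apply(fmt, axis=1)
    s["row"] = s["landmark"] + " — " + s["metric"] + " (" + s["units"] + ")"
    return s.pivot_table(index="row", columns="pair", values="cell", aggfunc="first")
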