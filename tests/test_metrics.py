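import numpy as np
import pytest

from laaoplan.geometry import Curve3D, Plane3D, Point3D
from laaoplan.metrics import (
    ComparisonRecord,
    curve_centroid_distance,
    curve_diameter_difference,
    dice,
    format_comparison_table,
    hausdorff,
    plane_angle,
    tabulate_comparison,
)
from laaoplan.volume_io import LabelMask


def cube_mask(lo, size, grid=24):
    data = np.zeros((grid, grid, grid), dtype=np.uint8)
    data[lo[0] : lo[0] + size, lo[1] : lo[1] + size, lo[2] : lo[2] + size] = 1
    return LabelMask(data, np.ones(3), np.zeros(3))


def circle(radius, center=(0.0, 0.0, 0.0), n=256):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.asarray(center) + radius * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros(n)], axis=1
    )
    return Curve3D(pts, closed=True)


def brute_force_hausdorff(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestDice:
    def test_identical_masks(self):
        m = cube_mask((2, 2, 2), 10)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice(cube_mask((0, 0, 0), 5), cube_mask((10, 10, 10), 5)) == 0.0

    def test_half_overlap_exact(self):
        a = cube_mask((0, 0, 0), 10)
        b = cube_mask((5, 0, 0), 10)
        assert dice(a, b) == pytest.approx(2 * 500 / 2000, abs=1e-12)

    def test_both_empty_defined_as_one(self):
        empty = LabelMask(np.zeros((4, 4, 4), dtype=np.uint8), np.ones(3), np.zeros(3))
        assert dice(empty, empty) == 1.0

    def test_grid_mismatch_rejected(self):
        a = cube_mask((0, 0, 0), 5)
        b = LabelMask(a.data.copy(), a.spacing * 2, a.origin)
        with pytest.raises(ValueError, match="grids"):
            dice(a, b)

    def test_invariant_under_joint_translation(self):
        a, b = cube_mask((2, 2, 2), 8), cube_mask((5, 2, 2), 8)
        a2, b2 = cube_mask((6, 6, 6), 8), cube_mask((9, 6, 6), 8)
        assert dice(a, b) == dice(a2, b2)

    def test_matches_exhaustive_count(self, rng):
        da = (rng.random((12, 12, 12)) > 0.5).astype(np.uint8)
        db = (rng.random((12, 12, 12)) > 0.5).astype(np.uint8)
        a = LabelMask(da, np.ones(3), np.zeros(3))
        b = LabelMask(db, np.ones(3), np.zeros(3))
        inter = sum(
            1
            for i in range(12)
            for j in range(12)
            for k in range(12)
            if da[i, j, k] and db[i, j, k]
        )
        expected = 2 * inter / (da.sum() + db.sum())
        assert dice(a, b) == pytest.approx(expected, abs=1e-9)


class TestHausdorff:
    def test_curve_vs_itself_is_zero(self):
        c = circle(20.0)
        assert hausdorff(c, c) == 0.0

    def test_concentric_circles_closed_form(self):
        assert hausdorff(circle(20.0, n=2048), circle(22.0, n=2048)) == pytest.approx(2.0, abs=0.01)

    def test_matches_brute_force_on_point_sets(self, rng):
        a = rng.normal(size=(150, 3))
        b = rng.normal(size=(200, 3)) + 0.5
        assert hausdorff(a, b) == pytest.approx(brute_force_hausdorff(a, b), abs=1e-9)

    def test_symmetric(self, rng):
        a = rng.normal(size=(60, 3))
        b = rng.normal(size=(80, 3))
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(np.zeros((0, 3)), np.zeros((3, 3)))


class TestCurveMetrics:
    def test_centroid_distance_of_translate_is_pythagorean(self):
        c = circle(15.0)
        assert curve_centroid_distance(c, c.translated((3.0, 4.0, 0.0))) == pytest.approx(5.0, abs=1e-9)

    def test_centroid_invariant_to_vertex_reindexing_and_subdivision(self):
        # same polyline traversed from a different start vertex, with one
        # segment subdivided: arclength weighting makes the centroid identical
        ca = circle(15.0, n=64)
        rolled = np.roll(ca.vertices, 17, axis=0)
        extra = 0.5 * (rolled[0] + rolled[1])  # midpoint vertex on a segment
        cb = Curve3D(np.insert(rolled, 1, extra, axis=0))
        assert curve_centroid_distance(ca, cb) < 1e-9

    def test_diameter_difference_signed_predicted_minus_truth(self):
        assert curve_diameter_difference(circle(10.0, n=4096), circle(12.0, n=4096)) == pytest.approx(
            -4.0, abs=1e-4
        )

    def test_diameter_difference_antisymmetric(self):
        a, b = circle(10.0), circle(12.0)
        assert curve_diameter_difference(a, b) == pytest.approx(-curve_diameter_difference(b, a))

    def test_open_curve_rejected_for_diameter(self):
        open_c = Curve3D(np.array([[0.0, 0, 0], [1.0, 0, 0]]), closed=False)
        with pytest.raises(ValueError):
            curve_diameter_difference(open_c, circle(10.0))


class TestPlaneAngle:
    def test_plane_vs_itself(self):
        p = Plane3D(Point3D(0, 0, 0), np.array([0.3, 0.4, 0.5]))
        assert plane_angle(p, p) == 0.0

    def test_flipped_normal_gives_zero(self):
        p = Plane3D(Point3D(0, 0, 0), np.array([0.0, 0, 1.0]))
        assert plane_angle(p, p.flipped()) == 0.0

    def test_forty_five_degrees_closed_form(self):
        a = Plane3D(Point3D(0, 0, 0), np.array([1.0, 0, 0]))
        b = Plane3D(Point3D(0, 0, 0), np.array([1.0, 1.0, 0]))
        assert plane_angle(a, b) == pytest.approx(45.0, abs=1e-9)

    def test_range_capped_at_ninety(self, rng):
        for _ in range(20):
            a = Plane3D(Point3D(0, 0, 0), rng.normal(size=3))
            b = Plane3D(Point3D(0, 0, 0), rng.normal(size=3))
            assert 0.0 <= plane_angle(a, b) <= 90.0


class TestTabulate:
    def _rec(self, case, value, landmark="ostium", metric="plane_angle", pair="model_vs_obs1"):
        return ComparisonRecord(case, landmark, metric, value, "deg", pair)

    def test_constant_records(self):
        recs = [self._rec(f"c{i}", 3.5) for i in range(4)]
        t = tabulate_comparison(recs)
        row = t.iloc[0]
        assert row["mean"] == pytest.approx(3.5)
        assert row["sd"] == pytest.approx(0.0)
        assert row["n"] == 4

    def test_sample_standard_deviation(self):
        recs = [self._rec("a", -1.0), self._rec("b", +1.0)]
        row = tabulate_comparison(recs).iloc[0]
        assert row["mean"] == pytest.approx(0.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))

    def test_empty_pair_reported_not_dropped(self):
        recs = [self._rec("a", 1.0), self._rec("b", 2.0)]
        t = tabulate_comparison(recs, pairs=["model_vs_obs1", "obs2_vs_obs1"])
        empty = t[t["pair"] == "obs2_vs_obs1"]
        assert len(empty) == 1
        assert empty.iloc[0]["n"] == 0
        formatted = format_comparison_table(t)
        assert "n/a" in formatted.values

    def test_singleton_cell_sd_is_na(self):
        t = tabulate_comparison([self._rec("only", 2.0)])
        assert t.iloc[0]["n"] == 1
        assert np.isnan(t.iloc[0]["sd"])
        assert "± n/a" in format_comparison_table(t).values[0][0]

    def test_signed_values_preserved(self):
        recs = [self._rec("a", -0.8, metric="perimeter_based_diameter_difference")]
        assert tabulate_comparison(recs).iloc[0]["mean"] == pytest.approx(-0.8)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            ComparisonRecord("c", "ostium", "angle", float("nan"), "deg", "p")
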