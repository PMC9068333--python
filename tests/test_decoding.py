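import numpy as np
import pytest
from scipy import ndimage

from laaoplan.decoding import (
    binarize,
    decode_curve,
    decode_plane,
    decode_point,
    refine_segmentation,
)
from laaoplan.geometry import Curve3D, Plane3D, Point3D
from laaoplan.label_encoding import encode_curve, encode_plane_split, encode_point
from laaoplan.metrics import dice, hausdorff, plane_angle
from laaoplan.volume_io import LabelMask, ProbabilityMask, VolumeGrid


def unit_grid(n=48, spacing=1.0):
    return VolumeGrid(np.zeros((n, n, n), dtype=np.float32), np.full(3, spacing), np.zeros(3))


def as_prob(mask: LabelMask) -> ProbabilityMask:
    return ProbabilityMask(mask.data.astype(float), mask.spacing, mask.origin)


def circle(radius=20.0, center=(32.0, 32.0, 32.0), n=128):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.asarray(center) + radius * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros(n)], axis=1
    )
    return Curve3D(pts, closed=True)


class TestBinarize:
    def test_threshold_is_inclusive(self):
        p = ProbabilityMask(np.full((4, 4, 4), 0.5), np.ones(3), np.zeros(3))
        out = binarize(p, 0.5)
        assert np.all(out.data == 1)

    def test_identity_on_hard_mask(self, rng):
        hard = (rng.random((8, 8, 8)) > 0.5).astype(float)
        p = ProbabilityMask(hard, np.ones(3), np.zeros(3))
        assert np.array_equal(binarize(p, 0.5).data, hard.astype(np.uint8))

    def test_count_matches_exhaustive_scan(self, rng):
        probs = rng.random((10, 10, 10))
        p = ProbabilityMask(probs, np.ones(3), np.zeros(3))
        for thr in (0.2, 0.5, 0.9):
            brute = sum(
                1
                for i in range(10)
                for j in range(10)
                for k in range(10)
                if probs[i, j, k] >= thr
            )
            assert int(binarize(p, thr).data.sum()) == brute

    def test_threshold_bounds_enforced(self):
        p = ProbabilityMask(np.zeros((2, 2, 2)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            binarize(p, 0.0)


class TestRefineSegmentation:
    def test_single_component_unchanged(self, rng):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[5:15, 5:15, 5:15] = 1
        m = LabelMask(data, np.ones(3), np.zeros(3))
        out = refine_segmentation(m, mode="largest_component")
        assert np.array_equal(out.data, data)

    def test_satellite_blob_removed(self):
        data = np.zeros((30, 30, 30), dtype=np.uint8)
        data[5:20, 5:20, 5:20] = 1
        data[25:27, 25:27, 25:26] = 1  # 4-voxel satellite
        m = LabelMask(data, np.ones(3), np.zeros(3))
        out = refine_segmentation(m, mode="largest_component")
        assert out.data[26, 26, 25] == 0
        assert np.array_equal(out.data[5:20, 5:20, 5:20], data[5:20, 5:20, 5:20])

    def test_watershed_recovers_eroded_prediction(self, phantom_case):
        # a too-tight network mask is pushed back to the intensity boundary
        _, volume, truth = phantom_case
        eroded = LabelMask(
            ndimage.binary_erosion(truth.laa_mask.data > 0, iterations=2).astype(np.uint8),
            truth.laa_mask.spacing,
            truth.laa_mask.origin,
        )
        refined = refine_segmentation(eroded, intensity=volume, mode="watershed", combine="union")
        assert dice(refined, truth.laa_mask) >= dice(eroded, truth.laa_mask)

    def test_refinement_stays_near_input(self, phantom_case):
        _, volume, truth = phantom_case
        m = truth.laa_mask
        refined = refine_segmentation(m, intensity=volume, mode="watershed", combine="union", watershed_band=3)
        allowed = ndimage.binary_dilation(m.data > 0, iterations=3)
        assert np.all(allowed[refined.data > 0])

    def test_empty_mask_rejected(self):
        m = LabelMask(np.zeros((4, 4, 4), dtype=np.uint8), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            refine_segmentation(m)


class TestDecodePoint:
    def test_round_trip_through_sphere_encoding(self):
        g = unit_grid()
        p = Point3D(20.3, 21.7, 22.1)
        decoded = decode_point(as_prob(encode_point(p, 5.0, g)))
        assert np.all(np.abs(decoded.to_array() - p.to_array()) <= 0.5)

    def test_single_voxel_gives_its_center(self):
        data = np.zeros((8, 8, 8))
        data[3, 4, 5] = 1.0
        p = ProbabilityMask(data, np.full(3, 2.0), np.array([1.0, 1.0, 1.0]))
        decoded = decode_point(p)
        assert np.allclose(decoded.to_array(), [7.0, 9.0, 11.0])

    def test_symmetric_pair_gives_midpoint(self):
        # two 26-adjacent voxels symmetric about their midpoint
        data = np.zeros((9, 9, 9))
        data[3, 4, 4] = data[4, 5, 5] = 1.0
        decoded = decode_point(ProbabilityMask(data, np.ones(3), np.zeros(3)))
        assert np.allclose(decoded.to_array(), [3.5, 4.5, 4.5])

    def test_empty_detection_rejected(self):
        p = ProbabilityMask(np.zeros((4, 4, 4)), np.ones(3), np.zeros(3))
        with pytest.raises(ValueError, match="no detection"):
            decode_point(p)


class TestDecodeCurve:
    def test_circle_round_trip_hausdorff_within_two_voxels(self):
        g = unit_grid(64)
        c = circle(20.0)
        decoded = decode_curve(as_prob(encode_curve(c, 3.0, g)))
        assert decoded.closed
        assert hausdorff(decoded, c) <= 2.0 * float(g.spacing[0])

    def test_circle_length_within_ten_percent(self):
        g = unit_grid(64)
        c = circle(20.0)
        decoded = decode_curve(as_prob(encode_curve(c, 3.0, g)))
        assert abs(decoded.length() - 2 * np.pi * 20.0) / (2 * np.pi * 20.0) < 0.10

    def test_decoded_curve_contained_in_tube(self):
        g = unit_grid(64)
        c = circle(20.0)
        tube_r = 3.0
        decoded = decode_curve(as_prob(encode_curve(c, tube_r, g)))
        dense_truth = c.densified(0.1)
        for v in decoded.vertices:
            assert np.linalg.norm(dense_truth - v, axis=1).min() <= tube_r + float(g.spacing[0])

    def test_open_tube_returns_open_curve(self):
        g = unit_grid()
        seg = Curve3D(np.array([[10.0, 24, 24], [38.0, 24, 24]]), closed=False)
        mask = encode_curve(seg, 3.0, g)
        with pytest.warns(UserWarning, match="open curve"):
            decoded = decode_curve(as_prob(mask))
        assert not decoded.closed


class TestDecodePlane:
    def test_axis_aligned_split_recovers_exact_normal(self):
        data = np.zeros((20, 20, 20), dtype=np.uint8)
        data[2:18, 2:18, 2:18] = 1
        data[10:18, 2:18, 2:18] = 2
        m = LabelMask(data, np.ones(3), np.zeros(3))
        plane = decode_plane(m)
        assert plane_angle(plane, Plane3D(Point3D(9.5, 9.5, 9.5), np.array([1.0, 0, 0]))) < 1e-6
        assert plane.point.x == pytest.approx(9.5, abs=1e-9)

    def test_flipping_labels_flips_normal(self):
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[2:14, 2:14, 2:14] = 1
        data[8:14, 2:14, 2:14] = 2
        m = LabelMask(data, np.ones(3), np.zeros(3))
        flipped = LabelMask(
            np.where(data == 1, 2, np.where(data == 2, 1, 0)).astype(np.uint8),
            m.spacing,
            m.origin,
        )
        n1 = decode_plane(m).normal
        n2 = decode_plane(flipped).normal
        assert np.allclose(n1, -n2)

    def test_phantom_ostium_round_trip(self, phantom_case):
        _, _, truth = phantom_case
        split = encode_plane_split(truth.laa_mask, truth.ostium_plane, tip=truth.laa_tip)
        decoded = decode_plane(split)
        assert plane_angle(decoded, truth.ostium_plane) <= 2.0
        # decoded boundary centroid on the tube axis, within a voxel of truth
        assert decoded.point.distance_to(truth.ostium_plane.point) <= 1.0

    def test_non_adjacent_labels_rejected(self):
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[1:4, 1:4, 1:4] = 1
        data[10:14, 10:14, 10:14] = 2
        with pytest.raises(ValueError, match="no boundary"):
            decode_plane(LabelMask(data, np.ones(3), np.zeros(3)))


def test_decoders_invariant_under_rigid_translation():
    delta = np.array([11.0, -4.5, 2.25])
    g0 = unit_grid(64)
    g1 = VolumeGrid(np.zeros_like(g0.data), g0.spacing, g0.origin + delta)
    p = Point3D(20.3, 21.7, 22.1)
    d0 = decode_point(as_prob(encode_point(p, 5.0, g0)))
    d1 = decode_point(as_prob(encode_point(Point3D.from_array(p.to_array() + delta), 5.0, g1)))
    assert np.allclose(d1.to_array() - d0.to_array(), delta, atol=1e-9)

    c = circle(15.0)
    e0 = hausdorff(decode_curve(as_prob(encode_curve(c, 3.0, g0))), c)
    e1 = hausdorff(decode_curve(as_prob(encode_curve(c.translated(delta), 3.0, g1))), c.translated(delta))
    assert e0 == pytest.approx(e1, abs=1e-9)
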