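"""Per-shoot angle/length measurement and canopy-level quantities."""

import numpy as np
import pytest

from shootdelta import (PointCloud, canopy_summary, convex_hull_volume,
                        length_density, measure_segments, oriented_bbox,
                        regression_metrics, shoot_angle, shoot_length,
                        skeletonize)
from shootdelta.exceptions import DegenerateGeometryError
from shootdelta.segmentation import ShootSegment
from shootdelta.traits import ShootTraits

from .oracles import (hull_volume_monte_carlo, polyline_length_brute,
                      r2_rmse_mae_brute)


def tube(start, end, n=400, jitter=0.001, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)[:, None]
    pts = np.asarray(start) + t * (np.asarray(end) - np.asarray(start))
    return pts + rng.normal(0, jitter, pts.shape)


class TestOrientedBbox:
    def test_z_segment(self):
        pts = tube([0, 0, 0], [0, 0, 1], jitter=0)
        axes, extents, _ = oriented_bbox(pts)
        assert abs(axes[0] @ [0, 0, 1]) == pytest.approx(1, abs=1e-9)
        assert extents[0] == pytest.approx(1.0)

    def test_axis_aligned_box_corners(self):
        corners = np.array([[x, y, z] for x in (0, 3) for y in (0, 2)
                            for z in (0, 1)], dtype=float)
        axes, extents, center = oriented_bbox(corners)
        np.testing.assert_allclose(sorted(extents), [1, 2, 3], atol=1e-9)
        np.testing.assert_allclose(center, [1.5, 1, 0.5], atol=1e-9)

    def test_rotated_ellipsoid_major_axis(self, rng):
        u = rng.normal(size=(4000, 3)) * [1.0, 0.2, 0.1]
        ang = np.radians(35)
        r = np.array([[np.cos(ang), 0, -np.sin(ang)], [0, 1, 0],
                      [np.sin(ang), 0, np.cos(ang)]])
        axes, _, _ = oriented_bbox(u @ r.T)
        truth = r @ [1, 0, 0]
        cosang = abs(axes[0] @ truth)
        assert np.degrees(np.arccos(min(cosang, 1))) < 2.0

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            oriented_bbox(np.zeros((1, 3)))


class TestShootAngle:
    @pytest.mark.parametrize("direction,expected", [
        ((0, 0, 1), 90.0),
        ((1, 0, 1), 45.0),
        ((3, 0, 4), 53.130),
        ((1, 0, 0), 0.0),
    ])
    def test_elevation_examples(self, direction, expected):
        pts = tube([0, 0, 0], direction, jitter=1e-5)
        assert shoot_angle(pts) == pytest.approx(expected, abs=0.1)

    def test_invariant_to_z_rotation_and_translation(self, rng):
        pts = tube([0, 0, 0], [0.3, 0.1, 0.5], jitter=0.0005)
        base = shoot_angle(pts)
        for _ in range(5):
            ang = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            r = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            moved = pts @ r.T + rng.uniform(-5, 5, 3)
            assert shoot_angle(moved) == pytest.approx(base, abs=1e-6)


class TestSkeletonize:
    def test_straight_segment_length(self):
        pts = tube([0, 0, 0], [0, 0, 1], n=1000, jitter=0.001, seed=3)
        for method in ("geodesic_bins", "laplacian"):
            poly = skeletonize(pts, method=method)
            assert 0.95 <= shoot_length(poly) <= 1.05

    def test_quarter_circle_arc(self):
        r = 0.5
        t = np.linspace(0, np.pi / 2, 800)
        arc = np.column_stack([r * np.cos(t), np.zeros_like(t), r * np.sin(t)])
        rng = np.random.default_rng(0)
        arc += rng.normal(0, 0.0005, arc.shape)
        poly = skeletonize(arc, bin_width=0.02)
        expect = np.pi / 2 * r  # 0.7854
        assert shoot_length(poly) == pytest.approx(expect, rel=0.05)

    def test_single_bin_collapses_to_node(self):
        pts = np.random.default_rng(1).normal(0, 0.002, (50, 3))
        poly = skeletonize(pts, bin_width=0.5)
        assert len(poly) == 1
        assert shoot_length(poly) == 0.0

    def test_length_at_least_endpoint_chord(self):
        pts = tube([0, 0, 0], [0.2, 0.3, 0.4], n=600, jitter=0.001, seed=5)
        poly = skeletonize(pts)
        chord = np.linalg.norm(poly[-1] - poly[0])
        assert shoot_length(poly) >= 0.99 * chord


class TestShootLength:
    def test_examples(self):
        assert shoot_length(np.array([[0, 0, 0], [0, 0, 1.0]])) == 1.0
        assert shoot_length(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]])) == 2.0

    def test_matches_pairwise_sum(self, rng):
        poly = rng.normal(size=(20, 3))
        assert shoot_length(poly) == pytest.approx(
            polyline_length_brute(poly), abs=1e-12)

    def test_rigid_invariance(self, rng):
        poly = rng.normal(size=(15, 3))
        base = shoot_length(poly)
        ang = 1.1
        r = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        assert shoot_length(poly @ r.T + [4, 5, 6]) == pytest.approx(base, abs=1e-9)


class TestHullVolume:
    def test_unit_cube(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        vol, degenerate = convex_hull_volume(corners)
        assert not degenerate
        assert vol == pytest.approx(1.0)

    def test_regular_tetrahedron(self):
        # edge length 1 → V = sqrt(2)/12
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / (2 * np.sqrt(2))
        vol, _ = convex_hull_volume(pts)
        assert vol == pytest.approx(np.sqrt(2) / 12, rel=1e-9)

    def test_coplanar_is_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        vol, degenerate = convex_hull_volume(pts)
        assert degenerate or vol == 0.0

    def test_against_monte_carlo(self, rng):
        pts = rng.normal(size=(300, 3))
        vol, _ = convex_hull_volume(pts)
        mc = hull_volume_monte_carlo(pts, None, n_samples=200_000, seed=9)
        assert vol == pytest.approx(mc, rel=0.02)

    def test_monotone_under_addition(self, rng):
        pts = rng.normal(size=(50, 3))
        vol1, _ = convex_hull_volume(pts)
        vol2, _ = convex_hull_volume(np.vstack([pts, rng.normal(size=(50, 3)) * 2]))
        assert vol2 >= vol1 - 1e-12


class TestDensityAndSummary:
    def test_quotients(self):
        assert length_density(10, 4) == 2.5
        assert length_density(0, 1) == 0.0
        assert length_density(7.3, 17.60) == pytest.approx(0.414773, abs=1e-6)

    def test_zero_volume_rejected(self):
        with pytest.raises(ZeroDivisionError):
            length_density(1.0, 0.0)

    def test_summary_identity_dv_l(self):
        corners = PointCloud(points=np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1.0)]))
        traits = [ShootTraits(segment_id=0, theta=45, length=1.0, chord=1.0,
                              n_points=10)]
        summary = canopy_summary(traits, corners)
        assert summary.shoot_count == 1
        assert summary.total_length == 1.0
        assert summary.length_density * summary.hull_volume == pytest.approx(
            summary.total_length, rel=1e-9)

    def test_empty_segment_list(self):
        corners = PointCloud(points=np.random.default_rng(0).normal(size=(10, 3)))
        summary = canopy_summary([], corners)
        assert summary.shoot_count == 0
        assert summary.total_length == 0.0
        assert summary.length_density == 0.0


class TestRegressionMetrics:
    def test_perfect_fit(self):
        r2, rmse, mae = regression_metrics([1, 2, 3], [1, 2, 3])
        assert (r2, rmse, mae) == (1.0, 0.0, 0.0)

    def test_offset_by_one(self):
        r2, rmse, mae = regression_metrics([2, 3, 4], [1, 2, 3])
        assert mae == 1.0
        assert rmse == 1.0
        assert r2 == pytest.approx(-0.5)

    def test_matches_textbook_formulas(self, rng):
        est, ref = rng.normal(size=100), rng.normal(size=100)
        got = regression_metrics(est, ref)
        np.testing.assert_allclose(got, r2_rmse_mae_brute(est, ref), atol=1e-12)

    def test_zero_variance_reference(self):
        with pytest.raises(ZeroDivisionError):
            regression_metrics([1, 2], [3, 3])


class TestMeasureSegments:
    def test_fills_segment_fields(self):
        pts = tube([0, 0, 0], [0.1, 0, 0.4], n=500, jitter=0.001)
        seg = ShootSegment(segment_id=0, point_ids=np.arange(len(pts)),
                           points=pts, provenance="AS")
        traits = measure_segments([seg])
        assert seg.length == traits[0].length > 0
        assert seg.theta == traits[0].theta
        assert traits[0].provenance == "AS"
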