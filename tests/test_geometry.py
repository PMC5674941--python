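"""Radius averaging, minimal enclosing circles, and circle-restricted means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_min_circle
from biofilmq import geometry
from biofilmq.errors import ValidationError

finite_coord = st.floats(-100, 100, allow_nan=False, allow_infinity=False)
point_sets = st.lists(st.tuples(finite_coord, finite_coord), min_size=1, max_size=16)


class TestAverageRadius:
    def test_constant_distance_points(self):
        th = 2 * np.pi * np.arange(16) / 16
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        assert geometry.average_radius(pts, (0, 0)) == pytest.approx(10.0)

    def test_mean_of_two_symmetric_rings(self):
        th = 2 * np.pi * np.arange(8) / 8
        pts = np.vstack(
            [
                np.column_stack([8 * np.cos(th), 8 * np.sin(th)]),
                np.column_stack([12 * np.cos(th), 12 * np.sin(th)]),
            ]
        )
        assert geometry.average_radius(pts, (0, 0)) == pytest.approx(10.0)

    def test_matches_per_point_distance_sum(self, rng):
        pts = rng.uniform(-50, 50, size=(16, 2))
        center = (3.0, -7.0)
        expected = sum(np.hypot(x - 3.0, y + 7.0) for x, y in pts) / 16
        assert geometry.average_radius(pts, center) == pytest.approx(expected, abs=1e-12)

    def test_empty_point_list_rejected(self):
        with pytest.raises(ValidationError):
            geometry.average_radius(np.empty((0, 2)), (0, 0))


class TestMinimalBoundingCircle:
    def test_points_on_common_circle(self):
        th = 2 * np.pi * np.arange(16) / 16
        pts = np.column_stack([100 + 50 * np.cos(th), 100 + 50 * np.sin(th)])
        c = geometry.minimal_bounding_circle(pts)
        assert (c.cx, c.cy, c.r) == pytest.approx((100, 100, 50), abs=1e-9)

    def test_two_point_diameter(self):
        c = geometry.minimal_bounding_circle([(0, 0), (10, 0)])
        assert (c.cx, c.cy, c.r) == pytest.approx((5, 0, 5))

    def test_single_and_duplicate_points(self):
        c = geometry.minimal_bounding_circle([(3, 4), (3, 4), (3, 4)])
        assert (c.cx, c.cy, c.r) == pytest.approx((3, 4, 0))

    def test_matches_exhaustive_oracle_on_random_sets(self, rng):
        for _ in range(60):
            pts = rng.uniform(0, 400, size=(16, 2))
            c = geometry.minimal_bounding_circle(pts)
            ox, oy, orr = brute_force_min_circle(pts)
            assert (c.cx, c.cy, c.r) == pytest.approx((ox, oy, orr), abs=1e-6)

    def test_matches_shapely_reference(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import MultiPoint

        for _ in range(30):
            pts = rng.uniform(0, 200, size=(16, 2))
            c = geometry.minimal_bounding_circle(pts)
            assert c.r == pytest.approx(shapely.minimum_bounding_radius(MultiPoint(pts.tolist())), abs=1e-6)

    @given(point_sets, st.permutations(range(16)), finite_coord, finite_coord)
    @settings(deadline=None, max_examples=60)
    def test_invariant_under_permutation_and_translation(self, pts, perm, dx, dy):
        pts = np.asarray(pts)
        c1 = geometry.minimal_bounding_circle(pts)
        shuffled = pts[[p for p in perm if p < len(pts)] or [0]]
        c2 = geometry.minimal_bounding_circle(np.vstack([shuffled, pts]))
        assert c2.r == pytest.approx(c1.r, abs=1e-7)
        c3 = geometry.minimal_bounding_circle(pts + np.array([dx, dy]))
        assert c3.r == pytest.approx(c1.r, abs=1e-6)
        assert (c3.cx, c3.cy) == pytest.approx((c1.cx + dx, c1.cy + dy), abs=1e-6)

    @given(point_sets)
    @settings(deadline=None, max_examples=60)
    def test_contains_all_points_with_boundary_contact(self, pts):
        pts = np.asarray(pts)
        c = geometry.minimal_bounding_circle(pts)
        d = np.hypot(pts[:, 0] - c.cx, pts[:, 1] - c.cy)
        assert (d <= c.r + 1e-9).all()
        if len(np.unique(pts, axis=0)) > 1:
            assert (np.abs(d - c.r) < 1e-6).sum() >= 2

    def test_inner_circle_contained_in_joint_circle(self, rng):
        inner = rng.uniform(40, 60, size=(16, 2))
        outer = rng.uniform(0, 100, size=(16, 2))
        ci = geometry.minimal_bounding_circle(inner)
        cj = geometry.minimal_bounding_circle(np.vstack([inner, outer]))
        center_gap = np.hypot(ci.cx - cj.cx, ci.cy - cj.cy)
        assert center_gap + ci.r <= cj.r + 1e-9


class TestMeanIntensityInCircle:
    def test_uniform_field(self):
        img = np.full((50, 50), 42.0)
        mean, count = geometry.mean_intensity_in_circle(img, geometry.Circle(25, 25, 10))
        assert mean == 42.0
        assert count > 0

    def test_half_plane_split_circle(self):
        img = np.zeros((101, 101))
        img[:, 51:] = 200.0
        circle = geometry.Circle(50.5, 50.0, 20.0)
        mean, count = geometry.mean_intensity_in_circle(img, circle)
        # independent per-pixel membership oracle
        ys, xs = np.mgrid[0:101, 0:101]
        mask = (xs - 50.5) ** 2 + (ys - 50.0) ** 2 <= 400.0
        assert count == mask.sum()
        assert mean == pytest.approx(img[mask].mean(), abs=1e-12)

    def test_zero_radius_at_integer_pixel(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        mean, count = geometry.mean_intensity_in_circle(img, geometry.Circle(3, 2, 0))
        assert (mean, count) == (img[2, 3], 1)

    def test_circle_outside_image_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            geometry.mean_intensity_in_circle(np.zeros((10, 10)), geometry.Circle(100, 100, 3))

    def test_full_cover_equals_global_mean(self, rng):
        img = rng.uniform(0, 255, size=(40, 40))
        mean, count = geometry.mean_intensity_in_circle(img, geometry.Circle(19.5, 19.5, 1000))
        assert count == 1600
        assert mean == pytest.approx(img.mean(), abs=1e-12)

    def test_mean_bounded_by_image_extremes(self, rng):
        img = rng.uniform(0, 255, size=(60, 60))
        mean, _ = geometry.mean_intensity_in_circle(img, geometry.Circle(30, 30, 12.3))
        assert img.min() <= mean <= img.max()
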