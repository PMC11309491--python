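"""Ellipse parameterisation, boundary intersection and overlap area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellalign.geometry import (CoincidentEllipsesError, EllipseSpec,
                                boundary_point, implicit_residual, intersect,
                                min_image, overlap_area)
from conftest import random_ellipse, random_overlapping_pair

SQ2 = np.sqrt(2.0)


def unit_circle(x, y):
    return EllipseSpec(np.array([x, y], float), 0.0, 1.0, 1.0)


class TestBoundaryPoint:
    @pytest.mark.parametrize("ellipse, theta, s, expected", [
        (unit_circle(0, 0), 0.0, 1.0, (1.0, 0.0)),
        (EllipseSpec(np.zeros(2), np.pi / 2, SQ2, 1 / SQ2), 0.0, 1.0,
         (0.0, SQ2)),
        (EllipseSpec(np.array([3.0, -1.0]), 1.234, 2.0, 0.5), 0.77, 0.0,
         (3.0, -1.0)),
    ])
    def test_examples(self, ellipse, theta, s, expected):
        assert boundary_point(ellipse, theta, s) == pytest.approx(expected,
                                                                  abs=1e-12)

    def test_boundary_points_satisfy_implicit_equation(self, rng):
        for _ in range(20):
            e = random_ellipse(rng)
            th = rng.uniform(0, 2 * np.pi)
            assert abs(implicit_residual(e, boundary_point(e, th))) < 1e-10


class TestMinImage:
    @pytest.mark.parametrize("disp, L, expected", [
        ((19.5, 0.0), 20.0, (-0.5, 0.0)),
        ((0.3, -0.2), 20.0, (0.3, -0.2)),
        ((10.0, 10.0), 20.0, (10.0, 10.0)),   # boundary case of (-L/2, L/2]
        ((-10.0, 0.0), 20.0, (10.0, 0.0)),
    ])
    def test_examples(self, disp, L, expected):
        assert min_image(disp, L) == pytest.approx(expected, abs=1e-12)

    @given(x=st.floats(-1e3, 1e3), L=st.floats(0.5, 100.0))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_in_half_open_box_and_periodic(self, x, L):
        y = min_image([x, 0.0], L)[0]
        assert -L / 2 < y <= L / 2 + 1e-9
        # differs from the input by an integer number of box lengths
        k = (x - y) / L
        assert abs(k - round(k)) < 1e-9


class TestIntersect:
    def test_two_unit_circles_closed_form(self):
        ct = intersect(unit_circle(0, 0), unit_circle(1, 0), 20.0)
        assert ct.K == 1
        # ordered so the anticlockwise arc from Y1 to Y2 lies inside cell j
        assert ct.points[0] == pytest.approx((0.5, -np.sqrt(3) / 2), abs=1e-9)
        assert ct.points[1] == pytest.approx((0.5, +np.sqrt(3) / 2), abs=1e-9)

    def test_orthogonal_congruent_ellipses_four_points(self):
        e1 = EllipseSpec(np.zeros(2), 0.0, SQ2, 1 / SQ2)
        e2 = EllipseSpec(np.zeros(2), np.pi / 2, SQ2, 1 / SQ2)
        ct = intersect(e1, e2, 20.0)
        assert ct.K == 2
        v = np.sqrt(2.0 / 5.0)
        got = sorted(map(tuple, np.round(ct.points, 9)))
        want = sorted({(sx * v, sy * v) for sx in (-1, 1) for sy in (-1, 1)})
        assert np.allclose(got, want, atol=1e-9)

    def test_disjoint_returns_none(self):
        assert intersect(unit_circle(0, 0), unit_circle(5, 0), 20.0) is None

    def test_minimum_image_wrap(self):
        ct = intersect(unit_circle(0.0, 0.0), unit_circle(19.5, 0.0), 20.0)
        assert ct is not None and ct.K == 1
        # second circle's minimum image sits at (-0.5, 0)
        assert ct.points[:, 0] == pytest.approx([-0.25, -0.25], abs=1e-9)

    def test_containment_flagged_both_directions(self):
        big = EllipseSpec(np.array([5.0, 5.0]), 0.0, 3.0, 2.0)
        small = EllipseSpec(np.array([5.5, 5.0]), 0.3, 1.0, 0.5)
        for a, b in ((big, small), (small, big)):
            ct = intersect(a, b, 20.0)
            assert ct.degenerate_flag == "containment"
            assert ct.K == 0 and len(ct.points) == 0

    def test_coincident_raises(self):
        with pytest.raises(CoincidentEllipsesError):
            intersect(unit_circle(1, 2), unit_circle(1, 2), 20.0)

    def test_points_on_both_boundaries_and_paired_arcs_inside(self, rng):
        for _ in range(50):
            e1, e2, ct = random_overlapping_pair(rng)
            # contact geometry lives in cell i's periodic image frame
            e2_img = EllipseSpec(
                e1.centre + min_image(e2.centre - e1.centre, 20.0),
                e2.alpha, e2.a, e2.b)
            for p in ct.points:
                assert abs(implicit_residual(e1, p)) < 1e-8
                assert abs(implicit_residual(e2_img, p)) < 1e-8
            # anticlockwise ordering: θ strictly increasing along the list
            assert np.all(np.diff(ct.thetas) > 0)
            # each paired arc's midpoint lies strictly inside cell j
            for k in range(ct.K):
                tm = 0.5 * (ct.thetas[2 * k] + ct.thetas[2 * k + 1])
                assert implicit_residual(e2_img, boundary_point(e1, tm)) < 0

    def test_point_count_always_0_2_or_4(self, rng):
        counts = set()
        for _ in range(300):
            e1 = random_ellipse(rng)
            e2 = random_ellipse(
                rng, centre=(e1.centre + rng.uniform(-3, 3, 2)) % 20.0)
            ct = intersect(e1, e2, 20.0)
            counts.add(0 if ct is None else len(ct.points))
        assert counts <= {0, 2, 4}
        assert {0, 2} <= counts     # both regimes exercised

    def test_intersection_symmetric_as_point_set(self, rng):
        for _ in range(30):
            e1, e2, ct = random_overlapping_pair(rng)
            ct_ji = intersect(e2, e1, 20.0)
            # same physical points (up to the periodic image shift)
            shift = min_image(e1.centre - e2.centre, 20.0) \
                - (e1.centre - e2.centre)
            got = sorted(map(tuple, np.round(ct_ji.points - shift, 7)))
            want = sorted(map(tuple, np.round(ct.points, 7)))
            assert np.allclose(got, want, atol=1e-6)

    def test_rigid_rotation_equivariance(self, rng):
        from cellalign.geometry import rotation_matrix
        for _ in range(20):
            e1, e2, ct = random_overlapping_pair(rng)
            # fold the pair into a wrap-free frame before rotating rigidly
            e2 = EllipseSpec(e1.centre + min_image(e2.centre - e1.centre, 20.0),
                             e2.alpha, e2.a, e2.b)
            ct = intersect(e1, e2, np.inf)
            phi = rng.uniform(0, 2 * np.pi)
            R = rotation_matrix(phi)
            f1 = EllipseSpec(R @ e1.centre, e1.alpha + phi, e1.a, e1.b)
            f2 = EllipseSpec(R @ e2.centre, e2.alpha + phi, e2.a, e2.b)
            ct2 = intersect(f1, f2, np.inf)
            got = sorted(map(tuple, np.round(ct2.points, 8)))
            want = sorted(map(tuple, np.round(ct.points @ R.T, 8)))
            assert np.allclose(got, want, atol=1e-8)


class TestQuarticAgainstPolynomialRootFinder:
    """The closed-form quartic used in the hot path, checked against
    numpy's companion-matrix root finder on the same polynomial."""

    def test_crossing_angles_match_np_roots(self, rng):
        from cellalign._kernels import _trig_coeffs
        checked = 0
        while checked < 50:
            e1, e2, ct = random_overlapping_pair(rng)
            w = min_image(e2.centre - e1.centre, 20.0)
            A, B, C, D, E, F = _trig_coeffs(
                w[0], w[1], np.cos(e1.alpha), np.sin(e1.alpha), e1.a, e1.b,
                np.cos(e2.alpha), np.sin(e2.alpha), e2.a, e2.b)
            c4 = A - D + F
            c3 = 2 * (E - B)
            c2 = -2 * A + 4 * C + 2 * F
            c1 = 2 * (B + E)
            c0 = A + D + F
            if abs(c4) < 1e-9:
                continue
            roots = np.roots([c4, c3, c2, c1, c0])
            real = roots[np.abs(roots.imag) < 1e-7].real
            ref = np.sort(2 * np.arctan(real) % (2 * np.pi))
            got = np.sort(np.asarray(ct.thetas) % (2 * np.pi))
            assert len(ref) == len(got)
            assert np.allclose(got, ref, atol=1e-7)
            checked += 1


class TestOverlapArea:
    def test_full_overlap_of_unit_disc(self):
        a = overlap_area(unit_circle(3, 3), unit_circle(3, 3), 20.0)
        assert a == pytest.approx(np.pi, rel=1e-6)

    def test_disjoint_is_zero(self):
        assert overlap_area(unit_circle(0, 0), unit_circle(5, 0), 20.0) == 0.0

    def test_circular_lens_closed_form(self):
        a = overlap_area(unit_circle(0, 0), unit_circle(1, 0), 20.0)
        assert a == pytest.approx(2 * np.pi / 3 - np.sqrt(3) / 2, rel=1e-6)

    def test_lens_area_across_random_distances(self, rng):
        for d in rng.uniform(0.05, 1.95, 100):
            got = overlap_area(unit_circle(0, 0), unit_circle(d, 0), 20.0)
            want = 2 * np.arccos(d / 2) - (d / 2) * np.sqrt(4 - d * d)
            assert got == pytest.approx(want, rel=1e-5)
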