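"""Unit and property tests for the section-geometry computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteogeom.csg import (
    chord_lengths,
    cortical_moments,
    normalize_theta,
    polygon_area,
    polygon_centroid,
    polygon_perimeter,
    principal_moments,
    rasterize_oracle,
    section_moduli,
)
from osteogeom.errors import GeometryError

from conftest import ellipse_polygon, random_star_annulus, regular_polygon

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == pytest.approx(1.0)

    def test_triangle(self):
        tri = [(0, 0), (2, 0), (0, 2)]
        assert polygon_area(tri) == pytest.approx(2.0)

    def test_regular_4096gon_matches_inscribed_formula(self):
        n = 4096
        poly = regular_polygon(n, 1.0)
        exact = 0.5 * n * math.sin(2 * math.pi / n)  # inscribed-polygon oracle
        assert polygon_area(poly) == pytest.approx(exact, rel=1e-12)
        assert polygon_area(poly) == pytest.approx(math.pi, abs=1e-5)

    def test_signed_orientation(self):
        assert polygon_area(UNIT_SQUARE, signed=True) == pytest.approx(1.0)
        assert polygon_area(UNIT_SQUARE[::-1], signed=True) == pytest.approx(-1.0)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            polygon_area([(0, 0), (1, 0)])


class TestPolygonPerimeter:
    def test_unit_square(self):
        assert polygon_perimeter(UNIT_SQUARE) == pytest.approx(4.0)

    def test_regular_hexagon(self):
        assert polygon_perimeter(regular_polygon(6, 1.0)) == pytest.approx(6.0)

    def test_regular_4096gon(self):
        n = 4096
        exact = n * 2.0 * math.sin(math.pi / n)
        per = polygon_perimeter(regular_polygon(n, 1.0))
        assert per == pytest.approx(exact, rel=1e-12)
        assert per == pytest.approx(2 * math.pi, abs=1e-5)


class TestPolygonCentroid:
    def test_offset_circle(self):
        poly = regular_polygon(512, 2.0, center=(3.0, -2.0))
        assert polygon_centroid(poly) == pytest.approx([3.0, -2.0], abs=1e-12)

    def test_unit_square(self):
        assert polygon_centroid(UNIT_SQUARE) == pytest.approx([0.5, 0.5])

    def test_l_shape(self):
        # decomposition oracle: three unit squares, area-weighted mean of
        # (.5,.5), (1.5,.5), (.5,1.5) = (5/6, 5/6)
        poly = [(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)]
        assert polygon_centroid(poly) == pytest.approx([5 / 6, 5 / 6])


class TestCorticalMoments:
    def test_circular_annulus(self):
        outer = regular_polygon(4096, 2.0)
        inner = regular_polygon(4096, 1.0)
        centroid, ix, iy, ixy = cortical_moments(outer, inner)
        assert centroid == pytest.approx([0.0, 0.0], abs=1e-12)
        assert ix == pytest.approx(15 * math.pi / 4, rel=1e-3)
        assert iy == pytest.approx(15 * math.pi / 4, rel=1e-3)
        assert ixy == pytest.approx(0.0, abs=1e-9)

    def test_rectangle_minus_rectangle(self):
        # w h^3 / 12 oracle: (2*4^3 - 1*2^3)/12 = 10, (4*2^3 - 2*1)/12 = 2.5
        outer = np.array([[-1, -2], [1, -2], [1, 2], [-1, 2]], dtype=float)
        inner = np.array([[-0.5, -1], [0.5, -1], [0.5, 1], [-0.5, 1]], dtype=float)
        _, ix, iy, ixy = cortical_moments(outer, inner)
        assert ix == pytest.approx(10.0, rel=1e-12)
        assert iy == pytest.approx(2.5, rel=1e-12)
        assert ixy == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        outer, inner = random_star_annulus(rng)
        c0, ix0, iy0, ixy0 = cortical_moments(outer, inner)
        shift = np.array([17.0, -5.0])
        c1, ix1, iy1, ixy1 = cortical_moments(outer + shift, inner + shift)
        assert c1 - shift == pytest.approx(c0, abs=1e-9)
        assert (ix1, iy1, ixy1) == pytest.approx((ix0, iy0, ixy0), rel=1e-9)

    def test_nesting_violation(self):
        outer = regular_polygon(64, 1.0)
        inner = regular_polygon(64, 1.0, center=(2.0, 0.0))
        with pytest.raises(GeometryError):
            cortical_moments(outer, inner)

    def test_clockwise_rejected(self):
        outer = regular_polygon(64, 2.0)
        with pytest.raises(GeometryError):
            cortical_moments(outer[::-1], regular_polygon(64, 1.0))


class TestPrincipalMoments:
    def test_symmetric(self):
        assert principal_moments(2.0, 2.0, 0.0) == (2.0, 2.0, 0.0)

    def test_diagonal(self):
        imin, imax, theta = principal_moments(1.0, 3.0, 0.0)
        assert (imin, imax) == (1.0, 3.0)
        assert theta == pytest.approx(0.0)

    def test_pure_shear(self):
        # eigenvalues of [[2,1],[1,2]] are 1 and 3; major axis at 45 degrees
        imin, imax, theta = principal_moments(2.0, 2.0, 1.0)
        assert imin == pytest.approx(1.0)
        assert imax == pytest.approx(3.0)
        assert theta == pytest.approx(math.pi / 4)

    def test_rotation_scan_oracle(self):
        """theta must locate the angle minimizing Ix(alpha) of the rotated section."""
        beta = math.radians(30.0)
        outer = ellipse_polygon(3.0, 1.0, rotation=beta)
        inner = ellipse_polygon(1.5, 0.5, rotation=beta)
        _, ix, iy, ixy = cortical_moments(outer, inner)
        imin, imax, theta = principal_moments(ix, iy, ixy)
        assert theta == pytest.approx(beta, abs=1e-6)
        # brute-force scan: rotating the axes by alpha, Ix(alpha) ranges
        # exactly over [Imin, Imax]
        alphas = np.linspace(0, math.pi, 721)
        ix_alpha = (0.5 * (ix + iy) + 0.5 * (ix - iy) * np.cos(2 * alphas)
                    - ixy * np.sin(2 * alphas))
        assert np.min(ix_alpha) == pytest.approx(imin, rel=1e-5)
        assert np.max(ix_alpha) == pytest.approx(imax, rel=1e-5)
        assert ix_alpha[np.argmin(np.abs(alphas - beta))] == pytest.approx(
            imin, rel=1e-5)

    @given(
        st.floats(0.1, 1e6),
        st.floats(0.1, 1e6),
        st.floats(-1e5, 1e5),
    )
    def test_tensor_identities(self, ix, iy, ixy):
        imin, imax, _ = principal_moments(ix, iy, ixy)
        assert imin + imax == pytest.approx(ix + iy, rel=1e-9)
        assert imax - imin == pytest.approx(
            2 * math.hypot(0.5 * (iy - ix), ixy),
            rel=1e-9, abs=1e-9 * (abs(ix) + abs(iy)))
        assert imin <= min(ix, iy) + 1e-9 * abs(imax)
        assert imax >= max(ix, iy) - 1e-9 * abs(imax)

    @given(st.floats(-math.pi / 2 + 1e-6, math.pi / 2))
    def test_normalize_theta_range(self, theta):
        t = normalize_theta(theta)
        assert -math.pi / 4 < t <= math.pi / 4 + 1e-15
        # folding preserves the principal-axis pair (angle mod pi/2)
        assert math.isclose((t - theta) % (math.pi / 2), 0.0, abs_tol=1e-9) or \
            math.isclose((t - theta) % (math.pi / 2), math.pi / 2, abs_tol=1e-9)


class TestChordLengths:
    def test_circle(self):
        poly = regular_polygon(4096, 2.0)
        dx, dy, dxt, dyt, rmax = chord_lengths(poly, (0.0, 0.0), 0.0)
        assert (dx, dy, dxt, dyt, rmax) == pytest.approx((2.0,) * 5, rel=1e-5)

    def test_axis_aligned_ellipse(self):
        poly = ellipse_polygon(3.0, 1.0)
        dx, dy, dxt, dyt, rmax = chord_lengths(poly, (0.0, 0.0), 0.0)
        assert (dx, dy, rmax) == pytest.approx((3.0, 1.0, 3.0), rel=1e-6)
        assert (dxt, dyt) == pytest.approx((3.0, 1.0), rel=1e-6)

    def test_rotated_ellipse_derotation(self):
        beta = math.radians(30.0)
        poly = ellipse_polygon(3.0, 1.0, rotation=beta)
        dx, dy, dxt, dyt, rmax = chord_lengths(poly, (0.0, 0.0), beta)
        assert rmax == pytest.approx(3.0, rel=1e-6)
        assert dxt == pytest.approx(3.0, rel=1e-6)
        assert dyt == pytest.approx(1.0, rel=1e-4)


class TestSectionModuli:
    def test_circular_annulus(self):
        ix = iy = 15 * math.pi / 4
        j = ix + iy
        zx, zy, zmin, zmax, zpol = section_moduli(
            ix, iy, ix, iy, j, 2.0, 2.0, 2.0, 2.0, 2.0)
        assert zx == pytest.approx(15 * math.pi / 8)
        assert zpol == pytest.approx(15 * math.pi / 4)
        assert zx == zy == zmin == zmax

    def test_solid_ellipse(self):
        ix, iy = 3 * math.pi / 4, 27 * math.pi / 4
        zx, zy, *_ = section_moduli(ix, iy, ix, iy, ix + iy,
                                    3.0, 1.0, 3.0, 1.0, 3.0)
        assert zx == pytest.approx(3 * math.pi / 4)
        assert zy == pytest.approx(9 * math.pi / 4)

    def test_zero_chord_rejected(self):
        with pytest.raises(GeometryError):
            section_moduli(1, 1, 1, 1, 2, 0.0, 1, 1, 1, 1)


class TestRasterizeOracle:
    def test_square_area_convergence(self):
        outer = UNIT_SQUARE * 1.0
        inner = regular_polygon(16, 1e-3, center=(0.5, 0.5))
        res = rasterize_oracle(outer, inner, 1e-3)
        assert res["cortical_area"] == pytest.approx(1.0, rel=5e-3)

    def test_annulus_moments(self):
        outer = regular_polygon(1024, 2.0)
        inner = regular_polygon(1024, 1.0)
        res = rasterize_oracle(outer, inner, 5e-3)
        assert res["Ix"] == pytest.approx(15 * math.pi / 4, rel=1e-2)
        assert res["J"] == pytest.approx(res["Ix"] + res["Iy"])

    def test_cell_size_precondition(self):
        outer = regular_polygon(64, 2.0)
        inner = regular_polygon(64, 1.0)
        with pytest.raises(GeometryError):
            rasterize_oracle(outer, inner, 1.0)

    def test_agrees_with_exact_moments_on_random_sections(self):
        rng = np.random.default_rng(12345)
        for _ in range(10):  # the full 50-pair sweep runs in test_acceptance
            outer, inner = random_star_annulus(rng)
            _, ix, iy, ixy = cortical_moments(outer, inner)
            ca = polygon_area(outer) - polygon_area(inner)
            diag = math.hypot(*(outer.max(0) - outer.min(0)))
            res = rasterize_oracle(outer, inner, diag / 400.0)
            assert res["cortical_area"] == pytest.approx(ca, rel=1e-2)
            assert res["Ix"] == pytest.approx(ix, rel=1e-2)
            assert res["Iy"] == pytest.approx(iy, rel=1e-2)


class TestScalingLaws:
    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_area_moment_modulus_scaling(self, scale):
        rng = np.random.default_rng(99)
        outer, inner = random_star_annulus(rng)
        c0, ix0, iy0, ixy0 = cortical_moments(outer, inner)
        c1, ix1, iy1, ixy1 = cortical_moments(outer * scale, inner * scale)
        a0 = polygon_area(outer) - polygon_area(inner)
        a1 = polygon_area(outer * scale) - polygon_area(inner * scale)
        assert a1 == pytest.approx(scale**2 * a0, rel=1e-9)
        assert ix1 == pytest.approx(scale**4 * ix0, rel=1e-9)
        assert iy1 == pytest.approx(scale**4 * iy0, rel=1e-9)
        d0 = chord_lengths(outer, c0, 0.0)
        d1 = chord_lengths(outer * scale, c1, 0.0)
        z0 = section_moduli(ix0, iy0, ix0, iy0, ix0 + iy0, *d0)
        z1 = section_moduli(ix1, iy1, ix1, iy1, ix1 + iy1, *d1)
        assert np.asarray(z1) == pytest.approx(scale**3 * np.asarray(z0), rel=1e-9)

    def test_rotation_by_minus_theta_zeroes_ixy(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            outer, inner = random_star_annulus(rng)
            beta = rng.uniform(0, math.pi)
            c, s = math.cos(beta), math.sin(beta)
            rot = np.array([[c, -s], [s, c]])
            _, ix, iy, ixy = cortical_moments(outer @ rot.T, inner @ rot.T)
            _, _, theta = principal_moments(ix, iy, ixy)
            c2, s2 = math.cos(-theta), math.sin(-theta)
            derot = np.array([[c2, -s2], [s2, c2]])
            _, _, _, ixy2 = cortical_moments(outer @ rot.T @ derot.T,
                                             inner @ rot.T @ derot.T)
            imax = principal_moments(ix, iy, ixy)[1]
            assert abs(ixy2) < 1e-6 * imax
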