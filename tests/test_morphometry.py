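"""Unit and property tests for the per-nucleus geometry pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from nucmorph.morphometry import (
    MorphometryError,
    compute_features,
    convex_hull,
    ellipse_perimeter,
    feret,
    fit_ellipse,
    mask_to_contour,
    min_area_rect,
    polygon_area,
    shape_factors,
)
from nucmorph.synthetic import ShapeSpec, gen_mask

from conftest import brute_force_width, random_blob_mask


# ---------------------------------------------------------------------------
# contour
# ---------------------------------------------------------------------------


class TestContour:
    def test_filled_rectangle_reduces_to_four_corners(self, rect_mask_40x20):
        c = mask_to_contour(rect_mask_40x20)
        assert len(c) == 4
        assert c[:, 0].max() - c[:, 0].min() == 39  # pixel-center extents
        assert c[:, 1].max() - c[:, 1].min() == 19

    def test_disk_shoelace_area_matches_analytic(self, disk_mask_r50):
        c = mask_to_contour(disk_mask_r50)
        assert polygon_area(c) == pytest.approx(math.pi * 50**2, rel=0.02)

    def test_too_few_foreground_pixels_rejected(self):
        m = np.zeros((9, 9), dtype=np.uint8)
        m[4, 4] = 1
        with pytest.raises(MorphometryError, match="foreground pixels"):
            mask_to_contour(m)

    def test_multi_component_mask_rejected(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[2:6, 2:6] = 1
        m[10:14, 10:14] = 1
        with pytest.raises(MorphometryError, match="components"):
            mask_to_contour(m, context="P1/patch/3")

    def test_non_binary_mask_rejected(self):
        m = np.zeros((10, 10), dtype=int)
        m[3:7, 3:7] = 2
        with pytest.raises(MorphometryError, match="non-binary"):
            mask_to_contour(m)

    def test_contour_vertices_are_foreground_pixel_centers(self):
        m = random_blob_mask(3)
        c = mask_to_contour(m)
        for x, y in c:
            assert m[int(y), int(x)] == 1
            assert x == int(x) and y == int(y)


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------


class TestConvexHull:
    def test_square_with_interior_points(self):
        pts = np.array(
            [[0, 0], [10, 0], [10, 10], [0, 10], [5, 5], [2, 7], [8, 3]], dtype=float
        )
        hull, area = convex_hull(pts)
        assert area == pytest.approx(100.0)
        assert len(hull) == 4

    def test_idempotent_on_convex_polygon(self):
        pts = np.array([[0, 0], [4, 0], [6, 3], [3, 6], [0, 4]], dtype=float)
        hull1, a1 = convex_hull(pts)
        hull2, a2 = convex_hull(hull1)
        assert a1 == pytest.approx(a2)
        assert {tuple(p) for p in hull1} == {tuple(p) for p in hull2}

    def test_hull_contains_every_input_point(self):
        import shapely

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(200, 2)) * 30
        hull, _ = convex_hull(pts)
        poly = shapely.Polygon(hull).buffer(1e-9)
        assert all(poly.covers(shapely.Point(p)) for p in pts)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(MorphometryError):
            convex_hull(pts)


# ---------------------------------------------------------------------------
# minimum-area rectangle
# ---------------------------------------------------------------------------


class TestMinAreaRect:
    def test_axis_aligned_rectangle_convention(self, rect_mask_40x20):
        hull, _ = convex_hull(mask_to_contour(rect_mask_40x20))
        r = min_area_rect(hull)
        assert r.angle == -90.0
        assert {round(r.width, 6), round(r.height, 6)} == {39.0, 19.0}

    def test_square_rotated_45_degrees(self):
        m = gen_mask(ShapeSpec(kind="rectangle", a=20, b=20, theta=45.0, grid=(101, 101)))
        hull, _ = convex_hull(mask_to_contour(m))
        r = min_area_rect(hull)
        assert r.angle == pytest.approx(-45.0, abs=1.0)
        assert r.width == pytest.approx(r.height, rel=0.02)

    def test_rect_area_at_least_hull_area(self):
        for seed in range(5):
            hull, hull_area = convex_hull(mask_to_contour(random_blob_mask(seed)))
            r = min_area_rect(hull)
            assert r.area >= hull_area - 1e-9

    def test_matches_angle_sweep_oracle_on_blobs(self):
        """Rotating calipers equals a 0.1-degree brute-force sweep."""
        angles = np.arange(0.0, 90.0, 0.1)
        for seed in range(20):
            hull, _ = convex_hull(mask_to_contour(random_blob_mask(seed)))
            r = min_area_rect(hull)
            sweep = min(
                brute_force_width(hull, a) * brute_force_width(hull, a + 90.0)
                for a in angles
            )
            assert r.area <= sweep * (1 + 1e-6)
            # the sweep grid itself can only be slightly above the optimum
            assert r.area == pytest.approx(sweep, rel=5e-4)

    def test_degenerate_hull_rejected(self):
        with pytest.raises(MorphometryError):
            min_area_rect(np.array([[0.0, 0.0], [1.0, 1.0]]))


# ---------------------------------------------------------------------------
# Feret diameters
# ---------------------------------------------------------------------------


class TestFeret:
    def test_circle_diameters(self, disk_mask_r50):
        hull, _ = convex_hull(mask_to_contour(disk_mask_r50))
        f = feret(hull)
        assert f.max_diameter == pytest.approx(100.0, rel=0.02)
        assert f.min_diameter == pytest.approx(100.0, rel=0.02)

    def test_rectangle_diagonal_and_width(self, rect_mask_40x20):
        hull, _ = convex_hull(mask_to_contour(rect_mask_40x20))
        f = feret(hull)
        assert f.max_diameter == pytest.approx(math.hypot(39, 19))
        assert f.min_diameter == pytest.approx(19.0)
        assert -180.0 <= f.max_angle <= 180.0
        assert -180.0 <= f.min_angle <= 180.0

    def test_matches_projection_sweep_oracle_on_blobs(self):
        angles = np.arange(0.0, 180.0, 0.1)
        for seed in range(20):
            hull, _ = convex_hull(mask_to_contour(random_blob_mask(seed + 100)))
            f = feret(hull)
            widths = [brute_force_width(hull, a) for a in angles]
            assert f.min_diameter <= min(widths) * (1 + 1e-6)
            assert f.min_diameter == pytest.approx(min(widths), rel=5e-4)
            # max Feret equals the max pairwise distance; the projection
            # sweep attains it at the maximizing direction
            assert f.max_diameter >= max(widths) * (1 - 1e-6)
            assert f.max_diameter == pytest.approx(max(widths), rel=5e-4)


# ---------------------------------------------------------------------------
# ellipse fit and perimeter
# ---------------------------------------------------------------------------


class TestEllipse:
    def test_recovers_analytic_ellipse(self):
        m = gen_mask(ShapeSpec(kind="ellipse", a=50, b=30, grid=(151, 151)))
        e = fit_ellipse(mask_to_contour(m))
        assert e.long_axis == pytest.approx(100.0, rel=0.02)
        assert e.short_axis == pytest.approx(60.0, rel=0.02)

    def test_recovers_circle(self):
        m = gen_mask(ShapeSpec(kind="disk", a=40, b=40, grid=(121, 121)))
        e = fit_ellipse(mask_to_contour(m))
        assert e.long_axis == pytest.approx(80.0, rel=0.02)
        assert e.short_axis == pytest.approx(80.0, rel=0.02)
        assert e.center[0] == pytest.approx(60.0, abs=0.5)
        assert e.center[1] == pytest.approx(60.0, abs=0.5)

    def test_area_consistent_with_axes(self):
        e = fit_ellipse(mask_to_contour(random_blob_mask(7)))
        assert e.area == pytest.approx(
            math.pi * (e.long_axis / 2) * (e.short_axis / 2), rel=1e-9
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(MorphometryError, match="5"):
            fit_ellipse(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))

    def test_matches_constrained_least_squares_oracle(self):
        """Algebraic fit agrees with a generic constrained minimizer.

        Independent oracle: minimize the algebraic conic residual
        sum (A x^2 + B xy + C y^2 + D x + E y + F)^2 subject to the
        ellipse normalization 4AC - B^2 = 1, via SLSQP, then convert the
        conic to geometric parameters.
        """
        contour = mask_to_contour(random_blob_mask(21))
        e = fit_ellipse(contour)
        x, y = contour[:, 0], contour[:, 1]

        def residual(c):
            A, B, C, D, E, F = c
            return float(np.sum((A * x * x + B * x * y + C * y * y + D * x + E * y + F) ** 2))

        def constraint(c):
            A, B, C, D, E, F = c
            return 4 * A * C - B * B - 1.0

        # start from a perturbed circle through the data
        cx0, cy0 = x.mean(), y.mean()
        r0 = np.hypot(x - cx0, y - cy0).mean()
        c0 = np.array([1.0, 0.0, 1.0, -2 * cx0, -2 * cy0, cx0**2 + cy0**2 - r0**2])
        c0 /= math.sqrt(max(4 * c0[0] * c0[2] - c0[1] ** 2, 1e-12))
        sol = optimize.minimize(
            residual, c0, constraints=[{"type": "eq", "fun": constraint}],
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
        )
        A, B, C, D, E, F = sol.x
        # conic -> geometric conversion
        M = np.array([[A, B / 2], [B / 2, C]])
        cc = np.linalg.solve(2 * M, [-D, -E])
        mu = A * cc[0] ** 2 + B * cc[0] * cc[1] + C * cc[1] ** 2 - F
        evals = np.linalg.eigvalsh(M / mu)
        axes = 2.0 / np.sqrt(evals)  # full axis lengths, descending
        assert cc[0] == pytest.approx(e.center[0], abs=1e-6)
        assert cc[1] == pytest.approx(e.center[1], abs=1e-6)
        assert max(axes) == pytest.approx(e.long_axis, rel=1e-6)
        assert min(axes) == pytest.approx(e.short_axis, rel=1e-6)


class TestEllipsePerimeter:
    def test_circle_limit_exact(self):
        assert ellipse_perimeter(80.0, 80.0) == pytest.approx(2 * math.pi * 40.0, rel=1e-12)

    def test_matches_arc_length_quadrature(self):
        a, b = 50.0, 30.0  # semi-axes of a 100 x 60 ellipse

        def arc(t):
            return math.hypot(a * math.sin(t), b * math.cos(t))

        exact, _ = integrate.quad(arc, 0, 2 * math.pi, limit=200)
        assert ellipse_perimeter(100.0, 60.0) == pytest.approx(exact, rel=1e-4)

    def test_degenerate_limit_approaches_four_a(self):
        # flat-ellipse limit: perimeter -> 4a; Ramanujan II is known to
        # undershoot by ~0.4% there
        p = ellipse_perimeter(100.0, 1e-6)
        assert p == pytest.approx(200.0, rel=0.005)

    def test_invalid_axes_rejected(self):
        with pytest.raises(MorphometryError):
            ellipse_perimeter(0.0, 0.0)
        with pytest.raises(MorphometryError):
            ellipse_perimeter(10.0, 20.0)


# ---------------------------------------------------------------------------
# shape factors and full pipeline
# ---------------------------------------------------------------------------


class TestShapeFactors:
    def test_circle_identities(self, disk_mask_r50):
        f = compute_features(disk_mask_r50)
        for v in (f.esf, f.sf1, f.sf2, f.elongation, f.csf):
            assert v == pytest.approx(1.0, rel=0.02)

    def test_esf_arithmetic(self):
        m = gen_mask(ShapeSpec(kind="ellipse", a=50, b=30, grid=(151, 151)))
        f = compute_features(m)
        assert f.esf == pytest.approx(0.6, abs=0.02)

    def test_convexity_one_when_ellipse_area_equals_hull_area(self):
        from nucmorph.morphometry import FeretResult, FittedEllipse

        e = FittedEllipse(center=(0, 0), long_axis=10, short_axis=10,
                          theta=0.0, perimeter=10 * math.pi, area=25 * math.pi)
        fr = FeretResult(max_diameter=10, max_angle=0, min_diameter=10, min_angle=90)
        *_, convexity = shape_factors(e, fr, hull_area=25 * math.pi)
        assert convexity == pytest.approx(1.0)

    def test_rotation_invariance_of_features(self):
        """Features of an ellipse are stable under orientation sweeps."""
        vals = {}
        for theta in (0.0, 15.0, 30.0, 60.0, 75.0):
            m = gen_mask(ShapeSpec(kind="ellipse", a=50, b=30, theta=theta, grid=(151, 151)))
            f = compute_features(m)
            vals[theta] = f
            assert f.esf == pytest.approx(0.6, abs=0.02)
        ref = vals[0.0]
        for theta, f in vals.items():
            for attr in ("esf", "csf", "sf1", "sf2", "elongation", "convexity"):
                assert getattr(f, attr) == pytest.approx(getattr(ref, attr), rel=0.02)

    def test_90_degree_lattice_rotation_is_exact(self):
        m = random_blob_mask(5)
        f0 = compute_features(m)
        f90 = compute_features(np.rot90(m).copy())
        for attr in ("esf", "csf", "sf1", "sf2", "elongation", "convexity", "hull_area"):
            assert getattr(f90, attr) == pytest.approx(getattr(f0, attr), rel=1e-9)
        assert f90.feret.max_diameter == pytest.approx(f0.feret.max_diameter, rel=1e-12)
        assert f90.feret.min_diameter == pytest.approx(f0.feret.min_diameter, rel=1e-12)

    def test_csf_decreases_with_ellipticity_at_fixed_area(self):
        """Circularity falls monotonically as esf goes 1.0 -> 0.2."""
        area = math.pi * 30 * 30
        csfs = []
        for esf in (1.0, 0.8, 0.6, 0.4, 0.2):
            a = math.sqrt(area / (math.pi * esf))
            m = gen_mask(ShapeSpec(kind="ellipse", a=a, b=a * esf, grid=(161, 161)))
            csfs.append(compute_features(m).csf)
        assert all(x > y for x, y in zip(csfs, csfs[1:]))

    def test_scale_equivariance(self):
        # base shape large enough that the ~half-pixel contour inset
        # stays below the 1% length tolerance
        f1 = compute_features(gen_mask(ShapeSpec(kind="ellipse", a=40, b=24, grid=(121, 121))))
        f3 = compute_features(gen_mask(ShapeSpec(kind="ellipse", a=80, b=48, grid=(201, 201))))
        k = 2.0
        assert f3.feret.max_diameter == pytest.approx(k * f1.feret.max_diameter, rel=0.01)
        assert f3.ellipse.long_axis == pytest.approx(k * f1.ellipse.long_axis, rel=0.01)
        assert f3.hull_area == pytest.approx(k**2 * f1.hull_area, rel=0.02)
        assert f3.ellipse.area == pytest.approx(k**2 * f1.ellipse.area, rel=0.02)
        for attr in ("esf", "csf", "sf1", "sf2", "elongation", "convexity"):
            assert getattr(f3, attr) == pytest.approx(getattr(f1, attr), rel=0.02)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariants_on_random_blobs(self, seed):
        """Ratio bounds and ordering invariants hold for arbitrary blobs."""
        f = compute_features(random_blob_mask(seed))
        assert 0 < f.esf <= 1
        assert 0 < f.sf2 <= 1
        assert f.elongation >= 1
        assert f.elongation == pytest.approx(1.0 / f.sf2, rel=1e-9)
        assert f.feret.max_diameter >= f.feret.min_diameter > 0
        assert f.hull_area <= f.rect.area + 1e-9
        # rotated min-area rectangle never beats the axis-aligned bbox
        hull, _ = convex_hull(mask_to_contour(random_blob_mask(seed)))
        bbox = (hull[:, 0].max() - hull[:, 0].min()) * (hull[:, 1].max() - hull[:, 1].min())
        assert f.rect.area <= bbox + 1e-9
        assert f.csf > 0 and f.convexity > 0 and f.sf1 > 0

    def test_error_annotated_with_nucleus_identity(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[2, 2] = 1
        with pytest.raises(MorphometryError, match=r"P7/patchA/42"):
            compute_features(m, "P7", "patchA", 42)
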