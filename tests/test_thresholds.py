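"""Piecewise-regression threshold analysis: fit recovery, intersection
arithmetic and critical-point propagation."""

import numpy as np
import pytest

from renalnmp.thresholds import (
    LineFit,
    Poly2Fit,
    TwoSegmentFit,
    fit_line,
    fit_poly2,
    fit_two_segment,
    intersect_lines,
    propagate_critical,
)

# coefficients of the published extraction/delivery and flow/pressure fits
LEFT = LineFit(-33.337, 109.43, 1.0, (0.0, 2.0))
RIGHT = LineFit(0.2292, 50.933, 1.0, (1.0, 9.0))
RBF_DO2 = LineFit(12.57, 1.3984, 0.97, (0.0, 9.0))
RBF_AP = Poly2Fit(0.0093, -3.2127, 297.6, 0.96, (90.0, 200.0))


class TestFitLine:
    def test_noiseless_recovery(self):
        xs = np.linspace(0.5, 8.0, 20)
        fit = fit_line(xs, 12.57 * xs + 1.3984)
        assert fit.slope == pytest.approx(12.57, abs=1e-9)
        assert fit.intercept == pytest.approx(1.3984, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_convention(self):
        fit = fit_line([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_normal_equations_oracle(self, rng):
        xs = rng.uniform(0, 10, 40)
        ys = 3.0 * xs - 2.0 + rng.normal(0, 1.0, 40)
        fit = fit_line(xs, ys)
        # independent oracle: solve X'X b = X'y directly
        X = np.column_stack([xs, np.ones_like(xs)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ ys)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_shuffle_invariance(self, rng):
        xs = rng.uniform(0, 5, 30)
        ys = 2 * xs + rng.normal(0, 0.5, 30)
        fit = fit_line(xs, ys)
        perm = rng.permutation(30)
        fit2 = fit_line(xs[perm], ys[perm])
        assert fit.slope == pytest.approx(fit2.slope)
        assert fit.r_squared == pytest.approx(fit2.r_squared)


class TestTwoSegment:
    def test_recovers_published_biphasic_lines(self):
        xs_l = np.linspace(0.2, 1.70, 10)
        xs_r = np.linspace(1.78, 9.0, 14)
        xs = np.r_[xs_l, xs_r]
        ys = np.r_[LEFT(xs_l), RIGHT(xs_r)]
        fit = fit_two_segment(xs, ys)
        assert not fit.no_breakpoint
        assert fit.left.slope == pytest.approx(-33.337, abs=1e-6)
        assert fit.left.intercept == pytest.approx(109.43, abs=1e-6)
        assert fit.right.slope == pytest.approx(0.2292, abs=1e-6)
        assert fit.right.intercept == pytest.approx(50.933, abs=1e-6)
        assert fit.left.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_single_line_flagged(self):
        xs = np.linspace(0, 10, 12)
        fit = fit_two_segment(xs, 2.0 * xs + 1.0)
        assert fit.no_breakpoint
        assert fit.left.slope == pytest.approx(2.0)

    def test_nested_model_sse(self, rng):
        xs = rng.uniform(0, 10, 30)
        ys = rng.normal(0, 1, 30)
        seg = fit_two_segment(xs, ys)
        single = fit_line(xs, ys)
        sse_single = np.sum((ys - single(xs)) ** 2)
        lmask = xs < seg.breakpoint
        sse_seg = (np.sum((ys[lmask] - seg.left(xs[lmask])) ** 2)
                   + np.sum((ys[~lmask] - seg.right(xs[~lmask])) ** 2))
        assert sse_seg <= sse_single + 1e-9

    def test_breakpoint_recovery_under_noise(self, rng):
        # parameter recovery: two known lines plus noise small relative to
        # the slope gap; breakpoint must land within one grid cell
        xs = np.linspace(0, 10, 60)
        true_b = 4.0
        ys = np.where(xs < true_b, -3.0 * xs + 12.0, 0.5 * xs - 2.0)
        ys = ys + rng.normal(0, 0.05, xs.size)
        fit = fit_two_segment(xs, ys)
        cell = xs[1] - xs[0]
        assert abs(fit.breakpoint - true_b) <= cell + 1e-9


class TestPoly2:
    def test_recovers_published_quadratic(self):
        xs = np.linspace(90, 200, 25)
        fit = fit_poly2(xs, RBF_AP(xs))
        assert fit.a == pytest.approx(0.0093, abs=1e-6)
        assert fit.b == pytest.approx(-3.2127, abs=1e-6)
        assert fit.c == pytest.approx(297.6, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_linear_data_zero_curvature(self):
        xs = np.linspace(0, 5, 10)
        fit = fit_poly2(xs, 2 * xs + 1)
        assert fit.a == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        xs = rng.uniform(-3, 3, 50)
        ys = 0.7 * xs**2 - xs + 2 + rng.normal(0, 0.3, 50)
        fit = fit_poly2(xs, ys)
        X = np.column_stack([xs**2, xs, np.ones_like(xs)])
        a, b, c = np.linalg.solve(X.T @ X, X.T @ ys)
        assert fit.a == pytest.approx(a, abs=1e-8)
        assert fit.b == pytest.approx(b, abs=1e-8)
        assert fit.c == pytest.approx(c, abs=1e-8)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_poly2([1.0, 1.0, 2.0], [1, 2, 3])


class TestIntersect:
    def test_published_lines_cross_at_critical_point(self):
        x, y = intersect_lines(LEFT, RIGHT)
        assert x == pytest.approx(1.7427, abs=1e-3)
        assert y == pytest.approx(51.33, abs=1e-2)

    def test_identical_lines_error(self):
        with pytest.raises(ValueError):
            intersect_lines(LEFT, LEFT)

    def test_symmetric_pair(self):
        a = LineFit(1.0, 0.0, 1.0, (-1, 1))
        b = LineFit(-1.0, 0.0, 1.0, (-1, 1))
        assert intersect_lines(a, b) == (pytest.approx(0.0), pytest.approx(0.0))


class TestPropagate:
    def test_published_coefficients_round_to_printed_thresholds(self):
        cp = propagate_critical(TwoSegmentFit(LEFT, RIGHT, 1.74),
                                RBF_DO2, RBF_AP)
        assert (cp.do2_crit, cp.ero2_crit, cp.rbf_crit, cp.vo2_crit,
                cp.ap_crit) == (1.7, 51.0, 23.0, 0.9, 155.0)
        assert cp.raw.do2_crit == pytest.approx(1.7427, abs=1e-3)

    def test_vo2_identity_for_arbitrary_fits(self):
        left = LineFit(-10.0, 70.0, 1.0, (0, 3))
        right = LineFit(1.0, 48.0, 1.0, (2, 9))
        cp = propagate_critical(TwoSegmentFit(left, right, 2.0),
                                LineFit(12.0, 0.0, 1.0, (0, 9)), RBF_AP)
        assert cp.vo2_crit == pytest.approx(
            round(cp.ero2_crit / 100 * cp.do2_crit, 1))

    def test_no_real_root_is_error(self):
        steep = Poly2Fit(1.0, 0.0, 1000.0, 1.0, (0, 10))  # min value 1000
        with pytest.raises(ValueError):
            propagate_critical(TwoSegmentFit(LEFT, RIGHT, 1.74),
                               RBF_DO2, steep)

    def test_continuity_under_small_perturbation(self):
        eps = 1e-6
        base = propagate_critical(TwoSegmentFit(LEFT, RIGHT, 1.74),
                                  RBF_DO2, RBF_AP).raw
        bumped = propagate_critical(
            TwoSegmentFit(LineFit(LEFT.slope, LEFT.intercept + eps, 1.0,
                                  LEFT.x_range), RIGHT, 1.74),
            RBF_DO2, RBF_AP).raw
        assert abs(bumped.do2_crit - base.do2_crit) < 1e-4
        assert abs(bumped.ap_crit - base.ap_crit) < 1e-3

    def test_collinear_input_rejected(self):
        single = LineFit(2.0, 1.0, 1.0, (0, 10))
        with pytest.raises(ValueError):
            propagate_critical(TwoSegmentFit(single, single, 5.0,
                                             no_breakpoint=True),
                               RBF_DO2, RBF_AP)
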