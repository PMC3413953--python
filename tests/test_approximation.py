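"""Trend fits against independent closed-form oracles, and extrapolation."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from setmix.approximation import (
    DegenerateDesignError,
    estimate_mz_rate,
    evaluate,
    fit_exponential,
    fit_linear,
    fit_quadratic,
    table2_report,
)
from setmix.rates import regression_points
from setmix.synthetic_data import constant_scenario, simulate_counts


def normal_equations_line(points):
    """Independent closed-form OLS line: slope = Sxy/Sxx through the centroid."""
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    n = len(x)
    xbar, ybar = sum(x) / n, sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    return slope, ybar - slope * xbar


def lagrange_parabola(points):
    """Interpolating parabola through three points, in monomial coefficients."""
    (x0, y0), (x1, y1), (x2, y2) = points
    a = (
        y0 / ((x0 - x1) * (x0 - x2))
        + y1 / ((x1 - x0) * (x1 - x2))
        + y2 / ((x2 - x0) * (x2 - x1))
    )
    b = (
        -y0 * (x1 + x2) / ((x0 - x1) * (x0 - x2))
        - y1 * (x0 + x2) / ((x1 - x0) * (x1 - x2))
        - y2 * (x0 + x1) / ((x2 - x0) * (x2 - x1))
    )
    c = (
        y0 * x1 * x2 / ((x0 - x1) * (x0 - x2))
        + y1 * x0 * x2 / ((x1 - x0) * (x1 - x2))
        + y2 * x0 * x1 / ((x2 - x0) * (x2 - x1))
    )
    return a, b, c


def _random_points(rng, n):
    x = rng.uniform(0, 100, size=n)
    while np.unique(x).size < 3:
        x = rng.uniform(0, 100, size=n)
    y = rng.uniform(1, 40, size=n)
    return list(zip(x.tolist(), y.tolist()))


class TestLinearFit:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for n in (3, 5, 10, 50):
            pts = _random_points(rng, n)
            fit = fit_linear(pts)
            slope, intercept = normal_equations_line(pts)
            assert fit.coefficients[0] == pytest.approx(slope, abs=1e-10)
            assert fit.coefficients[1] == pytest.approx(intercept, abs=1e-10)

    def test_collinear_points_fit_exactly(self):
        pts = [(x, 3.0 - 0.25 * x) for x in (10.0, 40.0, 70.0, 95.0)]
        fit = fit_linear(pts)
        assert fit.coefficients == pytest.approx((-0.25, 3.0), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_passes_through_centroid(self):
        rng = np.random.default_rng(7)
        pts = _random_points(rng, 12)
        fit = fit_linear(pts)
        xbar = np.mean([p[0] for p in pts])
        ybar = np.mean([p[1] for p in pts])
        assert evaluate(fit, xbar) == pytest.approx(ybar, abs=1e-9)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear([(10.0, 1.0), (10.0, 2.0)])


class TestQuadraticFit:
    @given(
        xs=st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=3,
                    unique=True),
        ys=st.lists(st.floats(0.1, 40, allow_nan=False), min_size=3, max_size=3),
    )
    def test_three_points_interpolated_exactly(self, xs, ys):
        xs = sorted(xs)
        assume(min(xs[1] - xs[0], xs[2] - xs[1]) > 0.5)  # well-conditioned design
        pts = list(zip(xs, ys))
        fit = fit_quadratic(pts)
        for x, y in pts:
            assert evaluate(fit, x) == pytest.approx(y, abs=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_lagrange_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = _random_points(rng, 3)
            fit = fit_quadratic(pts)
            assert fit.coefficients == pytest.approx(lagrange_parabola(pts), abs=1e-8)

    def test_overdetermined_matches_polyfit_path(self):
        rng = np.random.default_rng(11)
        pts = _random_points(rng, 25)
        fit = fit_quadratic(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        # independent route: normal equations on the monomial design
        design = np.vander(x, 3)
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.coefficients == pytest.approx(tuple(coef), abs=1e-8)

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_quadratic([(1.0, 1.0), (1.0, 2.0), (2.0, 3.0)])


class TestExponentialFit:
    def test_reduces_to_linear_fit_on_logs(self):
        rng = np.random.default_rng(19)
        pts = _random_points(rng, 8)
        fit = fit_exponential(pts)
        log_fit = fit_linear([(x, math.log(y)) for x, y in pts])
        assert fit.coefficients[1] == pytest.approx(log_fit.coefficients[0], abs=1e-12)
        assert math.log(fit.coefficients[0]) == pytest.approx(
            log_fit.coefficients[1], abs=1e-12
        )
        assert fit.r_squared == pytest.approx(log_fit.r_squared, abs=1e-12)

    def test_exact_exponential_recovered(self):
        pts = [(x, 5.0 * math.exp(-0.02 * x)) for x in (0.0, 25.0, 60.0, 90.0)]
        fit = fit_exponential(pts)
        assert fit.coefficients[0] == pytest.approx(5.0, rel=1e-10)
        assert fit.coefficients[1] == pytest.approx(-0.02, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_y_names_the_point(self):
        with pytest.raises(ValueError, match="point 1"):
            fit_exponential([(0.0, 1.0), (10.0, 0.0), (20.0, 2.0)])


class TestEvaluate:
    def test_at_zero_returns_constant_term(self):
        lin = fit_linear([(10.0, 20.0), (50.0, 10.0)])
        assert evaluate(lin, 0.0) == pytest.approx(lin.coefficients[1])
        exp = fit_exponential([(10.0, 20.0), (50.0, 10.0)])
        assert evaluate(exp, 0.0) == pytest.approx(exp.coefficients[0])

    def test_linear_extrapolation_is_exact_arithmetic(self):
        fit = fit_linear([(40.0, 13.0), (60.0, 8.0), (80.0, 5.0)])
        slope, intercept = fit.coefficients
        assert evaluate(fit, 100.0) == slope * 100.0 + intercept

    def test_no_clamping_below_zero(self):
        fit = fit_linear([(0.0, 10.0), (50.0, 0.0)])
        assert evaluate(fit, 100.0) == pytest.approx(-10.0)


class TestMzExtrapolation:
    def test_constant_mixture_noise_off_recovers_p(self):
        """With p = 2% exactly and no noise the line and parabola land on 2 at a
        100% share; the exponential, being convex, overshoots a straight-line
        decline and is upward-biased in this regime."""
        cohort = simulate_counts(constant_scenario(noise=False))
        est = estimate_mz_rate(regression_points(cohort, "total"))
        assert est.per_form["linear"] == pytest.approx(2.0, abs=0.5)
        assert est.per_form["quadratic"] == pytest.approx(2.0, abs=0.5)
        assert est.per_form["exponential"] > 2.0
        assert est.headline == est.per_form["exponential"]
        assert not est.linear_is_lower_bound

    def test_negative_linear_extrapolation_flagged(self):
        pts = [(40.0, 13.0), (60.0, 7.0), (80.0, 4.0)]
        est = estimate_mz_rate(pts)
        assert est.per_form["linear"] < 0
        assert est.linear_is_lower_bound


class TestReportTable:
    def test_constant_mixture_report_shapes(self):
        """Zero-noise constant (p, q): the line has slope -(q-p)/100 and the
        parabola collapses to it (leading coefficient ~ 0)."""
        cohort = simulate_counts(constant_scenario(noise=False))
        report = table2_report(cohort, methods=("total",))
        lin = report["total"]["linear"]
        assert lin["coefficients"][0] == pytest.approx(-0.24, abs=0.005)
        assert lin["coefficients"][1] == pytest.approx(26.0, abs=0.1)
        quad = report["total"]["quadratic"]
        assert quad["coefficients"][0] == pytest.approx(0.0, abs=1e-3)

    def test_insufficient_years_is_informative(self, fixture_cohort):
        from setmix.registry_data import Cohort

        two_years = Cohort(
            tuple(r for r in fixture_cohort if r.year < 2009 and r.method == "total")
        )
        with pytest.raises(DegenerateDesignError, match="total"):
            table2_report(two_years, methods=("total",))
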