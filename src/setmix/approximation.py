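"""Trend fitting of the multiple pregnancy rate against the SET pregnancy share.

Y (multiple pregnancy rate, percent) is regressed on X (SET pregnancy rate,
percent) with three functional forms:

* linear      Y = slope*X + intercept          (ordinary least squares)
* quadratic   Y = a*X^2 + b*X + c              (OLS on the monomial design;
                                                exact interpolation at 3 points)
* exponential Y = A*exp(B*X)                   (OLS of ln Y on X; R^2 on the
                                                log scale)

Extrapolating a fit to X = 100 — every pregnancy after a single-embryo
transfer — estimates the multiple pregnancy rate that SET alone would produce,
i.e. the monozygotic twinning rate after SET.  A linear extrapolation can go
negative there and is then flagged rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .registry_data import Cohort
from .rates import regression_points, round_half_up

__all__ = [
    "FitResult",
    "DegenerateDesignError",
    "fit_linear",
    "fit_quadratic",
    "fit_exponential",
    "evaluate",
    "estimate_mz_rate",
    "MZEstimate",
    "table2_report",
    "REPORT_METHODS",
]

#: Minimum points per functional form.
_MIN_POINTS = {"linear": 2, "quadratic": 3, "exponential": 2}


class DegenerateDesignError(ValueError):
    """Too few distinct X values for the requested functional form."""


@dataclass(frozen=True)
class FitResult:
    """A fitted trend with its goodness of fit on the fitting scale.

    ``coefficients`` are ordered (slope, intercept) for linear, (a, b, c) for
    quadratic, (A, B) for exponential.  For the exponential form ``r_squared``
    is computed on the natural-log scale where the fit is linear;
    ``r_squared_raw`` additionally records the raw-scale value.
    """

    form: str
    coefficients: tuple[float, ...]
    r_squared: float
    n_points: int
    x_range: tuple[float, float]
    r_squared_raw: Optional[float] = None


def _as_xy(points: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (X, Y) pairs")
    return pts[:, 0], pts[:, 1]


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        # constant response: call the fit perfect iff residuals are at rounding level
        scale = max(1.0, float(np.sum(y**2)))
        return 1.0 if ss_res <= 1e-16 * scale else 0.0
    return 1.0 - ss_res / ss_tot


def _require_design(x: np.ndarray, form: str) -> None:
    n_distinct = np.unique(x).size
    need = _MIN_POINTS[form]
    if x.size < need or n_distinct < need:
        raise DegenerateDesignError(
            f"{form} fit needs >= {need} points with {need} distinct X; "
            f"got {x.size} points, {n_distinct} distinct"
        )


def _lstsq(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def fit_linear(points: Sequence[tuple[float, float]]) -> FitResult:
    """Ordinary least squares line through percent-scale (X, Y) pairs."""
    x, y = _as_xy(points)
    _require_design(x, "linear")
    design = np.column_stack([x, np.ones_like(x)])
    slope, intercept = _lstsq(design, y)
    fitted = design @ (slope, intercept)
    return FitResult(
        form="linear",
        coefficients=(float(slope), float(intercept)),
        r_squared=_r_squared(y, fitted),
        n_points=x.size,
        x_range=(float(x.min()), float(x.max())),
    )


def fit_quadratic(points: Sequence[tuple[float, float]]) -> FitResult:
    """Least-squares parabola; with exactly three points, exact interpolation."""
    x, y = _as_xy(points)
    _require_design(x, "quadratic")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    a, b, c = _lstsq(design, y)
    fitted = design @ (a, b, c)
    return FitResult(
        form="quadratic",
        coefficients=(float(a), float(b), float(c)),
        r_squared=_r_squared(y, fitted),
        n_points=x.size,
        x_range=(float(x.min()), float(x.max())),
    )


def fit_exponential(points: Sequence[tuple[float, float]]) -> FitResult:
    """Fit Y = A*exp(B*X) by OLS of ln Y on X.

    All Y must be strictly positive.  ``r_squared`` is the log-scale value (the
    scale on which the least-squares problem is solved); the raw-scale value is
    kept alongside in ``r_squared_raw``.
    """
    x, y = _as_xy(points)
    _require_design(x, "exponential")
    bad = np.nonzero(y <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"exponential fit requires Y > 0; point {i} is (X={x[i]}, Y={y[i]})"
        )
    log_y = np.log(y)
    design = np.column_stack([x, np.ones_like(x)])
    b_coef, log_a = _lstsq(design, log_y)
    a_coef = math.exp(log_a)
    fitted_log = design @ (b_coef, log_a)
    return FitResult(
        form="exponential",
        coefficients=(float(a_coef), float(b_coef)),
        r_squared=_r_squared(log_y, fitted_log),
        n_points=x.size,
        x_range=(float(x.min()), float(x.max())),
        r_squared_raw=_r_squared(y, np.exp(fitted_log)),
    )


def evaluate(fit: FitResult, x: float) -> float:
    """Evaluate a fitted form at X (percent), at full coefficient precision.

    Extrapolations are returned unclamped; a negative value signals that the
    functional form has left its region of validity.
    """
    if fit.form == "linear":
        slope, intercept = fit.coefficients
        return slope * x + intercept
    if fit.form == "quadratic":
        a, b, c = fit.coefficients
        return a * x * x + b * x + c
    if fit.form == "exponential":
        a_coef, b_coef = fit.coefficients
        return a_coef * math.exp(b_coef * x)
    raise TypeError(f"unknown form {fit.form!r}")


@dataclass(frozen=True)
class MZEstimate:
    """Per-form extrapolations of the multiple pregnancy rate to a 100% SET share.

    ``headline`` is the exponential-form value: the exponential stays positive
    by construction and tracks the flattening of the trend near high SET
    shares, where the line crosses zero.  A negative linear value is kept as a
    flagged lower bound, not discarded.
    """

    per_form: dict[str, float]
    headline: float
    linear_is_lower_bound: bool

    def to_dict(self) -> dict:
        return {
            "estimates_at_100_percent_set": self.per_form,
            "headline_mz_rate_percent": self.headline,
            "linear_flagged_negative": self.linear_is_lower_bound,
        }


def estimate_mz_rate(points: Sequence[tuple[float, float]]) -> MZEstimate:
    """Extrapolate all three fitted forms to X = 100 and summarize.

    The headline monozygotic-twinning estimate is the exponential form's value;
    the linear value is reported as a flagged lower bound when negative.
    """
    per_form = {
        form: evaluate(fit_fn(points), 100.0)
        for form, fit_fn in (
            ("linear", fit_linear),
            ("quadratic", fit_quadratic),
            ("exponential", fit_exponential),
        )
    }
    return MZEstimate(
        per_form=per_form,
        headline=per_form["exponential"],
        linear_is_lower_bound=per_form["linear"] < 0.0,
    )


#: Method groups reported in the approximation table, in report order.
REPORT_METHODS = ("fresh-IVF-ET", "fresh-ICSI", "frozen", "total")

_FITTERS = {
    "linear": fit_linear,
    "quadratic": fit_quadratic,
    "exponential": fit_exponential,
}


def _format_r2(r2: float) -> str:
    rounded = round_half_up(r2, 3)
    return "1" if rounded == 1.0 else f"{rounded:.3f}"


def _signed(value: float, ndigits: int) -> str:
    """' + 1.23' / ' - 1.23' continuation term at fixed rounding."""
    r = round_half_up(value, ndigits)
    sign = "-" if r < 0 else "+"
    return f" {sign} {abs(r):.{ndigits}f}"


def _trim(value: float, ndigits: int) -> str:
    """Fixed rounding with trailing zeros trimmed, table-style (-0.030 -> -0.03)."""
    text = f"{round_half_up(value, ndigits):.{ndigits}f}"
    return text.rstrip("0").rstrip(".") if "." in text else text


def _format_formula(fit: FitResult) -> str:
    r2 = _format_r2(fit.r_squared)
    if fit.form == "linear":
        slope, intercept = fit.coefficients
        return f"Y = {round_half_up(slope, 2):.2f}X{_signed(intercept, 2)} (R^2 = {r2})"
    if fit.form == "quadratic":
        a, b, c = fit.coefficients
        return (
            f"Y = {round_half_up(a, 4):.4f}X^2{_signed(b, 2)}X{_signed(c, 2)} "
            f"(R^2 = {r2})"
        )
    a_coef, b_coef = fit.coefficients
    return f"Y = {round_half_up(a_coef, 3):.3f}exp({_trim(b_coef, 3)}X) (R^2 = {r2})"


def table2_report(cohort: Cohort, methods: Sequence[str] = REPORT_METHODS) -> dict:
    """Fit all three forms per method group and lay the results out table-style.

    For each method: the formula string at presentation rounding, the
    full-precision coefficients and R^2, and the extrapolation Y(100) at full
    coefficient precision.  ``y100_full_precision_reproducible`` records which
    extrapolation cells are expected to match a source that evaluated some
    formulas with display-rounded coefficients: linear extrapolations are
    robust to this, quadratic ones are not (the X^2 term amplifies the rounding
    of the leading coefficient by 10^4 at X = 100), and exponential ones only
    when the rounded and full-precision decay constants coincide.
    """
    report: dict[str, dict] = {}
    for method in methods:
        pts = regression_points(cohort, method)
        if len(pts) < 3:
            raise DegenerateDesignError(
                f"method {method!r} has {len(pts)} yearly points; >= 3 required"
            )
        entry: dict[str, dict] = {}
        for form, fitter in _FITTERS.items():
            fit = fitter(pts)
            y100 = evaluate(fit, 100.0)
            entry[form] = {
                "formula": _format_formula(fit),
                "coefficients": fit.coefficients,
                "r_squared": fit.r_squared,
                "y_at_100": y100,
                "y100_full_precision_reproducible": _y100_reproducible(form, fit),
            }
        report[method] = entry
    return report


def _y100_reproducible(form: str, fit: FitResult) -> bool:
    if form == "linear":
        return True
    if form == "quadratic":
        return False
    # exponential: stable only if rounding B to 2-3 significant decimals is a no-op
    a_coef, b_coef = fit.coefficients
    full = a_coef * math.exp(b_coef * 100.0)
    rounded = round_half_up(a_coef, 3) * math.exp(round_half_up(b_coef, 3) * 100.0)
    return abs(full - rounded) < 5e-3


def plot_fits(points: Sequence[tuple[float, float]], path: str) -> None:
    """Convenience scatter of Y against X with the three fitted curves (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _as_xy(points)
    grid = np.linspace(min(x.min(), 0.0), 100.0, 200)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, color="black", zorder=3, label="observed")
    for form, fitter in _FITTERS.items():
        fit = fitter(points)
        ax.plot(grid, [evaluate(fit, g) for g in grid], label=form)
    ax.set_xlabel("SET pregnancy rate (%)")
    ax.set_ylabel("multiple pregnancy rate (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
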