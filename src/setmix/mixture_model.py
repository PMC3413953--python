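"""Two-component mixture of multiple-pregnancy risk by embryo-transfer type.

In a given year, let ``s`` be the share of ART pregnancies that followed a
single-embryo transfer (SET), ``p`` the multiple-pregnancy probability given a
SET pregnancy (essentially monozygotic splitting), and ``q`` the probability
given a non-SET (mostly double-embryo) pregnancy.  The population multiple
pregnancy rate is then the mixture

    M = s*p + (1 - s)*q = q - (q - p)*s,

decomposable into a SET contribution ``S = s*p`` and a non-SET contribution
``D = (1 - s)*q``.  For ``q > p``, M falls linearly in ``s`` with slope
``-(q - p)``; the intercepts identify ``q`` at ``s = 0`` and ``p`` at ``s = 1``.

Internally everything is on the fraction scale (0-1); percent conversion
happens only in the interpretation layer, which maps fitted percent-scale
regression lines back to the mixture parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .approximation import FitResult

__all__ = [
    "MixtureParams",
    "LinearInterpretation",
    "total_multiple_rate",
    "invert_for_q",
    "interpret_linear_fit",
]


class DomainError(ValueError):
    """A mixture parameter lies outside its admissible range."""


@dataclass(frozen=True)
class MixtureParams:
    """One point of the mixture: shares and the derived rates, all fractions."""

    s: float  #: SET share of pregnancies, in [0, 1]
    p: float  #: multiple probability given SET pregnancy, in (0, 1]
    q: float  #: multiple probability given non-SET pregnancy, in (0, 1]

    @property
    def S(self) -> float:
        """SET contribution s*p to the total multiple rate."""
        return self.s * self.p

    @property
    def D(self) -> float:
        """Non-SET contribution (1-s)*q."""
        return (1.0 - self.s) * self.q

    @property
    def M(self) -> float:
        """Total multiple pregnancy rate q - (q - p)*s."""
        return self.q - (self.q - self.p) * self.s


def total_multiple_rate(s: float, p: float, q: float) -> MixtureParams:
    """Evaluate the mixture at (s, p, q), all fractions.

    ``s`` must lie in [0, 1]; ``p`` and ``q`` in (0, 1].  The returned object
    carries M, S and D as derived properties; M is decreasing in ``s`` exactly
    when ``q > p``.
    """
    if not 0.0 <= s <= 1.0:
        raise DomainError(f"s={s} outside [0, 1]")
    if not 0.0 < p <= 1.0:
        raise DomainError(f"p={p} outside (0, 1]")
    if not 0.0 < q <= 1.0:
        raise DomainError(f"q={q} outside (0, 1]")
    return MixtureParams(s=s, p=p, q=q)


def invert_for_q(gap_points: float, p_points: float) -> float:
    """Recover q (percent) from the risk gap q - p and p, both in percentage points.

    The magnitude of a fitted percent-on-percent slope, times 100, estimates the
    gap; adding the SET multiple rate back gives the non-SET rate.  E.g. a gap
    of 24 points with p = 2% gives q = 26%.
    """
    if gap_points < 0 or p_points < 0:
        raise DomainError("gap and p must be nonnegative")
    return gap_points + p_points


@dataclass(frozen=True)
class LinearInterpretation:
    """Mixture reading of a percent-scale linear trend of M against s.

    All values in percent / percentage points.  ``p_hat`` is the line's
    extrapolation to a 100% SET share; a negative value means the linear form
    has left its region of validity near s = 1 and is flagged.
    """

    q_hat: float  #: intercept: non-SET multiple rate at s = 0
    gap_hat: float  #: q - p, from the slope magnitude x 100
    p_hat: float  #: extrapolated SET (monozygotic) multiple rate at s = 1
    p_hat_valid: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "q_hat_percent": self.q_hat,
            "gap_hat_points": self.gap_hat,
            "p_hat_percent": self.p_hat,
            "p_hat_valid": self.p_hat_valid,
            "note": self.note,
        }


def interpret_linear_fit(fit: "FitResult") -> LinearInterpretation:
    """Map a fitted line Y = slope*X + intercept (percent scales) to (q, q-p, p).

    The intercept estimates q; minus the slope, times 100 when X is percent,
    estimates the gap q - p in points; the value at X = 100 estimates p.
    A near-constant gap over the fitted X range is what makes the line a good
    description in the first place.
    """
    if fit.form != "linear":
        raise TypeError(f"expected a linear fit, got {fit.form!r}")
    slope, intercept = fit.coefficients
    p_hat = slope * 100.0 + intercept
    valid = p_hat >= 0.0
    return LinearInterpretation(
        q_hat=intercept,
        gap_hat=-slope * 100.0,
        p_hat=p_hat,
        p_hat_valid=valid,
        note=(
            ""
            if valid
            else "extrapolation below zero -- linear form invalid near s = 1"
        ),
    )
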