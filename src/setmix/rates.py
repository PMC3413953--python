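"""Derived surveillance rates, in percent, from registry counts.

Four rates per (year, method) cell:

* SET pregnancy rate — SET pregnancies / all pregnancies.  This is the share of
  pregnancies that followed a single-embryo transfer, *not* the per-transfer
  success rate of SET.
* multiple pregnancy rate — multiple pregnancies / all pregnancies.
* non-SET multiple pregnancy rate — multiple pregnancies / (pregnancies - SET
  pregnancies); undefined when every pregnancy followed SET.
* total pregnancy rate per implantation — pregnancies / transfer cycles.

Rates are carried at full floating precision; presentation rounding (half-up,
one decimal, matching how registries print these tables) is opt-in, and
downstream regressions must consume the full-precision values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .registry_data import Cohort, CountRecord

__all__ = ["RateRecord", "UndefinedRateError", "compute_rates", "rate_table", "round_half_up"]


class UndefinedRateError(ZeroDivisionError):
    """A rate's denominator is zero."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in printed registry tables."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateRecord:
    """The four derived percentages for one count record.

    ``nonset_multiple_pregnancy_rate`` is ``None`` when all pregnancies followed
    SET (denominator zero).
    """

    year: int
    method: str
    set_pregnancy_rate: float
    multiple_pregnancy_rate: float
    nonset_multiple_pregnancy_rate: Optional[float]
    total_pregnancy_rate: float

    def rounded(self, ndigits: int = 1) -> "RateRecord":
        return replace(
            self,
            set_pregnancy_rate=round_half_up(self.set_pregnancy_rate, ndigits),
            multiple_pregnancy_rate=round_half_up(self.multiple_pregnancy_rate, ndigits),
            nonset_multiple_pregnancy_rate=(
                None
                if self.nonset_multiple_pregnancy_rate is None
                else round_half_up(self.nonset_multiple_pregnancy_rate, ndigits)
            ),
            total_pregnancy_rate=round_half_up(self.total_pregnancy_rate, ndigits),
        )


def compute_rates(record: CountRecord) -> RateRecord:
    """Derive the four percent-scale rates for one record.

    Raises :class:`UndefinedRateError` when the record has no pregnancies.
    When all pregnancies followed SET the non-SET multiple rate is returned as
    ``None`` and the other three rates normally.
    """
    if record.n_pregnancies == 0:
        raise UndefinedRateError(
            f"({record.year}, {record.method}): no pregnancies; rates undefined"
        )
    n_nonset = record.n_nonset_pregnancies
    return RateRecord(
        year=record.year,
        method=record.method,
        set_pregnancy_rate=100.0 * record.n_set_pregnancies / record.n_pregnancies,
        multiple_pregnancy_rate=100.0 * record.n_multiple_pregnancies / record.n_pregnancies,
        nonset_multiple_pregnancy_rate=(
            None if n_nonset == 0 else 100.0 * record.n_multiple_pregnancies / n_nonset
        ),
        total_pregnancy_rate=100.0 * record.n_pregnancies / record.n_implantations,
    )


def rate_table(cohort: Cohort, rounding: bool = False) -> list[RateRecord]:
    """One :class:`RateRecord` per count record, in cohort order.

    With ``rounding`` on, every rate is rounded half-up to one decimal, the
    registry presentation convention.  Errors from individual records are
    re-raised with the (year, method) context.
    """
    out = []
    for rec in cohort:
        try:
            rr = compute_rates(rec)
        except UndefinedRateError:
            raise
        out.append(rr.rounded() if rounding else rr)
    return out


def rate_frame(cohort: Cohort, rounding: bool = True):
    """Presentation table: one row per (year, method), the four rates plus their
    numerator/denominator strings, as a pandas DataFrame ready for CSV."""
    import pandas as pd

    columns = [
        "year", "method",
        "set_pregnancy_rate", "set_pregnancy_counts",
        "multiple_pregnancy_rate", "multiple_pregnancy_counts",
        "nonset_multiple_pregnancy_rate", "nonset_multiple_counts",
        "total_pregnancy_rate", "total_pregnancy_counts",
    ]
    rows = []
    for rec, rr in zip(cohort, rate_table(cohort, rounding=rounding)):
        rows.append(
            {
                "year": rec.year,
                "method": rec.method,
                "set_pregnancy_rate": rr.set_pregnancy_rate,
                "set_pregnancy_counts": f"{rec.n_set_pregnancies}/{rec.n_pregnancies}",
                "multiple_pregnancy_rate": rr.multiple_pregnancy_rate,
                "multiple_pregnancy_counts": f"{rec.n_multiple_pregnancies}/{rec.n_pregnancies}",
                "nonset_multiple_pregnancy_rate": rr.nonset_multiple_pregnancy_rate,
                "nonset_multiple_counts": f"{rec.n_multiple_pregnancies}/{rec.n_nonset_pregnancies}",
                "total_pregnancy_rate": rr.total_pregnancy_rate,
                "total_pregnancy_counts": f"{rec.n_pregnancies}/{rec.n_implantations}",
            }
        )
    return pd.DataFrame(rows, columns=columns)


def regression_points(cohort: Cohort, method: str) -> list[tuple[float, float]]:
    """(X, Y) pairs for trend fitting: full-precision SET pregnancy rate (X)
    against multiple pregnancy rate (Y), both percent, one pair per year."""
    sub = cohort.filter(method)
    return [
        (r.set_pregnancy_rate, r.multiple_pregnancy_rate)
        for r in rate_table(sub, rounding=False)
    ]
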