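"""Annual ART registry count tables: data model, CSV I/O, and the JSOG 2007-2009 fixture.

The unit of observation is one (year, ART method) cell of a national registry's
aggregate counts: transfer cycles ("implantations" in registry usage), pregnancies
(gestational sac ascertained, ectopic included), pregnancies after single embryo
transfer (SET), and multiple pregnancies.  Counts for multiples *among* SET
pregnancies are carried as an optional field: national reports do not publish
them, but the synthetic generator does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "METHODS",
    "CountRecord",
    "Cohort",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "jsog_fixture",
]

#: Controlled vocabulary of ART-method labels.
METHODS = ("fresh-IVF-ET", "fresh-ICSI", "frozen", "other", "total")

#: CSV column order, fixed so files round-trip byte-stably.
CSV_COLUMNS = (
    "year",
    "method",
    "n_implantations",
    "n_pregnancies",
    "n_set_pregnancies",
    "n_multiple_pregnancies",
    "n_set_multiple_pregnancies",
)


class FormatError(ValueError):
    """A delimited file does not have the expected columns or cell types."""


class ValidationError(ValueError):
    """A count record violates a structural invariant."""


@dataclass(frozen=True)
class CountRecord:
    """Registry counts for one calendar year and one ART method.

    Invariants (checked on construction):

    * ``0 <= n_set_pregnancies <= n_pregnancies <= n_implantations``
    * ``0 <= n_multiple_pregnancies <= n_pregnancies``
    * if present, ``n_set_multiple_pregnancies <= min(n_set_pregnancies,
      n_multiple_pregnancies)``
    """

    year: int
    method: str
    n_implantations: int
    n_pregnancies: int
    n_set_pregnancies: int
    n_multiple_pregnancies: int
    n_set_multiple_pregnancies: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        counts = {
            "n_implantations": self.n_implantations,
            "n_pregnancies": self.n_pregnancies,
            "n_set_pregnancies": self.n_set_pregnancies,
            "n_multiple_pregnancies": self.n_multiple_pregnancies,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be nonnegative, got {value}")
        if self.n_set_pregnancies > self.n_pregnancies:
            raise ValidationError(
                f"({self.year}, {self.method}): n_set_pregnancies "
                f"{self.n_set_pregnancies} > n_pregnancies {self.n_pregnancies}"
            )
        if self.n_pregnancies > self.n_implantations:
            raise ValidationError(
                f"({self.year}, {self.method}): n_pregnancies "
                f"{self.n_pregnancies} > n_implantations {self.n_implantations}"
            )
        if self.n_multiple_pregnancies > self.n_pregnancies:
            raise ValidationError(
                f"({self.year}, {self.method}): n_multiple_pregnancies "
                f"{self.n_multiple_pregnancies} > n_pregnancies {self.n_pregnancies}"
            )
        if self.n_set_multiple_pregnancies is not None:
            cap = min(self.n_set_pregnancies, self.n_multiple_pregnancies)
            if not (0 <= self.n_set_multiple_pregnancies <= cap):
                raise ValidationError(
                    f"({self.year}, {self.method}): n_set_multiple_pregnancies "
                    f"{self.n_set_multiple_pregnancies} outside [0, {cap}]"
                )

    @property
    def n_nonset_pregnancies(self) -> int:
        return self.n_pregnancies - self.n_set_pregnancies


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of :class:`CountRecord` with unique (year, method) keys."""

    records: tuple[CountRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        keys = [(r.year, r.method) for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (year, method) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CountRecord]:
        return iter(self.records)

    def get(self, year: int, method: str) -> CountRecord:
        for rec in self.records:
            if rec.year == year and rec.method == method:
                return rec
        raise KeyError((year, method))

    def filter(self, method: str) -> "Cohort":
        """Sub-cohort for one ART method, input order preserved."""
        return Cohort(
            tuple(r for r in self.records if r.method == method),
            label=f"{self.label}[{method}]" if self.label else f"[{method}]",
        )

    @property
    def methods(self) -> tuple[str, ...]:
        seen: list[str] = []
        for rec in self.records:
            if rec.method not in seen:
                seen.append(rec.method)
        return tuple(seen)


def _cell_to_optional_int(value: object, column: str, row: int) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row}: column {column!r} has non-numeric value {value!r}")
    if as_float != int(as_float):
        raise FormatError(f"row {row}: column {column!r} must be an integer, got {value!r}")
    return int(as_float)


def read_counts(path: str | Path) -> Cohort:
    """Read a registry-count CSV into a validated :class:`Cohort`.

    The file must carry a header naming at least the six mandatory columns of
    :data:`CSV_COLUMNS`; ``n_set_multiple_pregnancies`` may be absent or empty.

    Raises
    ------
    FormatError
        missing column or non-integer cell.
    ValidationError
        a row violates a :class:`CountRecord` invariant; the message names the row.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=object)
    mandatory = [c for c in CSV_COLUMNS if c != "n_set_multiple_pregnancies"]
    missing = [c for c in mandatory if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    has_set_mult = "n_set_multiple_pregnancies" in frame.columns

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))
        year = _cell_to_optional_int(row_d["year"], "year", i)
        if year is None:
            raise FormatError(f"row {i}: column 'year' is empty")
        counts = {}
        for col in mandatory[2:]:
            value = _cell_to_optional_int(row_d[col], col, i)
            if value is None:
                raise FormatError(f"row {i}: column {col!r} is empty")
            counts[col] = value
        set_mult = (
            _cell_to_optional_int(
                row_d["n_set_multiple_pregnancies"], "n_set_multiple_pregnancies", i
            )
            if has_set_mult
            else None
        )
        try:
            records.append(
                CountRecord(
                    year=year,
                    method=str(row_d["method"]),
                    n_set_multiple_pregnancies=set_mult,
                    **counts,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return Cohort(tuple(records), label=str(path))


def write_counts(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV (UTF-8, comma-separated, one header row).

    ``read_counts(write_counts(c))`` returns a cohort with identical records.
    """
    rows = []
    for rec in cohort:
        rows.append(
            {
                "year": rec.year,
                "method": rec.method,
                "n_implantations": rec.n_implantations,
                "n_pregnancies": rec.n_pregnancies,
                "n_set_pregnancies": rec.n_set_pregnancies,
                "n_multiple_pregnancies": rec.n_multiple_pregnancies,
                "n_set_multiple_pregnancies": (
                    "" if rec.n_set_multiple_pregnancies is None
                    else rec.n_set_multiple_pregnancies
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)


# JSOG aggregate registry counts, 2007-2009, by published method group.
# Cells are (year, method, implantations, pregnancies, SET pregnancies, multiples).
# "total" rows are stored as published, not recomputed by summing the method
# groups: the published totals include small unlisted methods such as GIFT.
_JSOG_CELLS = (
    (2007, "fresh-IVF-ET", 27729, 7313, 3017, 926),
    (2008, "fresh-IVF-ET", 28609, 6808, 4082, 513),
    (2009, "fresh-IVF-ET", 28075, 6818, 4725, 397),
    (2007, "fresh-ICSI", 29768, 6577, 2585, 746),
    (2008, "fresh-ICSI", 29831, 5934, 3314, 425),
    (2009, "fresh-ICSI", 30604, 6186, 3921, 354),
    (2007, "frozen", 43452, 13932, 7757, 1376),
    (2008, "frozen", 56494, 18194, 12913, 1086),
    (2009, "frozen", 69979, 22813, 17500, 1079),
    (2007, "total", 105849, 29165, 13865, 3221),
    (2008, "total", 121395, 32511, 21232, 2139),
    (2009, "total", 135093, 37437, 27330, 1917),
)


def jsog_fixture() -> Cohort:
    """The embedded JSOG 2007-2009 aggregate cohort (12 year x method records).

    The Japanese national ART registry publishes aggregate counts only; SET
    multiples are not broken out, so ``n_set_multiple_pregnancies`` is absent.
    The "frozen" label covers the registry's intra-uterine frozen transfers.
    """
    records = tuple(
        CountRecord(
            year=year,
            method=method,
            n_implantations=impl,
            n_pregnancies=preg,
            n_set_pregnancies=set_preg,
            n_multiple_pregnancies=mult,
        )
        for year, method, impl, preg, set_preg, mult in _JSOG_CELLS
    )
    return Cohort(records, label="JSOG 2007-2009")
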