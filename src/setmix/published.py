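"""Published analysis values for the bundled JSOG 2007-2009 registry cohort.

The national annual reports and their published trend analysis print, per ART
method group, the four surveillance rates at one decimal and three fitted
approximation formulas with extrapolations to a 100% SET share.  These
constants let the `report` command juxtapose what this package computes
against what was published, cell by cell.

Some published extrapolation cells were evidently evaluated with
display-rounded coefficients (the quadratic Y(100) values and the frozen
exponential one); those cells carry ``exact=False`` and are compared loosely.
"""

from __future__ import annotations

#: Published linear / quadratic / exponential cells per method group:
#: (slope, intercept, R^2), (a, b, c, R^2), (A, B, R^2), and Y(100) per form.
#: R^2 printed as 1 means "rounds to 1.000".
PUBLISHED_TABLE2 = {
    "fresh-IVF-ET": {
        "linear": {"slope": -0.25, "intercept": 22.78, "r2": 0.992, "y100": -2.04, "y100_exact": True},
        "quadratic": {"a": 0.0032, "b": -0.61, "c": 31.98, "r2": 1.0, "y100": 3.79, "y100_exact": False},
        "exponential": {"A": 39.704, "B": -0.028, "r2": 1.0, "y100": 2.41, "y100_exact": False},
    },
    "fresh-ICSI": {
        "linear": {"slope": -0.24, "intercept": 20.58, "r2": 0.996, "y100": -3.08, "y100_exact": True},
        "quadratic": {"a": 0.0026, "b": -0.50, "c": 26.90, "r2": 1.0, "y100": 3.25, "y100_exact": False},
        "exponential": {"A": 34.578, "B": -0.028, "r2": 1.0, "y100": 2.10, "y100_exact": False},
    },
    "frozen": {
        "linear": {"slope": -0.25, "intercept": 23.60, "r2": 0.999, "y100": -1.09, "y100_exact": True},
        "quadratic": {"a": 0.0019, "b": -0.49, "c": 31.51, "r2": 1.0, "y100": 1.22, "y100_exact": False},
        "exponential": {"A": 68.083, "B": -0.035, "r2": 0.998, "y100": 2.06, "y100_exact": False},
    },
    "total": {
        "linear": {"slope": -0.24, "intercept": 22.20, "r2": 0.996, "y100": -1.40, "y100_exact": True},
        "quadratic": {"a": 0.0024, "b": -0.52, "c": 30.52, "r2": 1.0, "y100": 2.03, "y100_exact": False},
        "exponential": {"A": 46.148, "B": -0.030, "r2": 0.999, "y100": 2.30, "y100_exact": True},
    },
}

#: Published one-decimal rate cells, per (year, method):
#: (SET pregnancy rate, multiple rate, non-SET multiple rate, pregnancy rate).
PUBLISHED_TABLE1 = {
    (2007, "fresh-IVF-ET"): (41.3, 12.7, 21.6, 26.4),
    (2008, "fresh-IVF-ET"): (60.0, 7.5, 18.8, 23.8),
    (2009, "fresh-IVF-ET"): (69.3, 5.8, 19.0, 24.3),
    (2007, "fresh-ICSI"): (39.3, 11.3, 18.7, 22.1),
    (2008, "fresh-ICSI"): (55.8, 7.2, 16.2, 19.9),
    (2009, "fresh-ICSI"): (63.4, 5.7, 15.6, 20.2),
    (2007, "frozen"): (55.7, 9.9, 22.3, 32.1),
    (2008, "frozen"): (71.0, 6.0, 20.6, 32.2),
    (2009, "frozen"): (76.7, 4.7, 20.3, 32.6),
    (2007, "total"): (47.5, 11.0, 21.1, 27.6),
    (2008, "total"): (65.3, 6.6, 19.0, 26.8),
    (2009, "total"): (73.0, 5.1, 19.0, 27.7),
}
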