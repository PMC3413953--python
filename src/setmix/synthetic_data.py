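"""Synthetic registry cohorts with the generative structure the analysis assumes.

A :class:`Scenario` specifies, per calendar year, the SET share of pregnancies
``s``, the SET (monozygotic) multiple probability ``p``, the non-SET multiple
probability ``q``, and per ART method a cohort size and pregnancy probability.
:func:`simulate_counts` turns a scenario into registry-shaped count tables by
binomial sampling; :func:`three_period_scenario` builds the reverse-sigmoid
uptake trajectory in which the multiple-rate-vs-SET-share curve passes through
three phases — convex-up (cap-shaped) while ART success is still improving and
``q`` rises, near-linear while ``p`` and ``q`` are stable, convex-down
(cup-shaped) once ``q`` declines and monozygotic twinning after SET puts a
floor under the curve.

National registries publish aggregates with no stated sampling model; the
binomial noise here is this package's own assumption, chosen as the simplest
count-valued mechanism consistent with the mixture decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .approximation import fit_linear
from .mixture_model import DomainError, interpret_linear_fit
from .rates import regression_points
from .registry_data import Cohort, CountRecord

__all__ = [
    "Scenario",
    "TrajectoryPoint",
    "three_period_scenario",
    "constant_scenario",
    "simulate_counts",
    "recovery_experiment",
    "RecoverySummary",
]


@dataclass(frozen=True)
class TrajectoryPoint:
    """One year of the generative trajectory, all quantities fractions."""

    year: int
    s: float
    p: float
    q: float
    period_label: str  # convex-up | linear | convex-down

    @property
    def M(self) -> float:
        return self.q - (self.q - self.p) * self.s


@dataclass(frozen=True)
class Scenario:
    """A generative trajectory for a synthetic registry.

    ``n_implantations`` and ``pregnancy_prob`` are per ART-method label and
    constant over years; the (s, p, q) trajectories are shared across methods
    and aligned with ``years``.  ``noise`` toggles binomial sampling versus
    deterministic rounded expectations.
    """

    years: tuple[int, ...]
    n_implantations: dict[str, int]
    pregnancy_prob: dict[str, float]
    s_trajectory: tuple[float, ...]
    p_trajectory: tuple[float, ...]
    q_trajectory: tuple[float, ...]
    period_labels: tuple[str, ...] = ()
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("s_trajectory", "p_trajectory", "q_trajectory"):
            traj = getattr(self, name)
            if len(traj) != n:
                raise DomainError(f"{name} has {len(traj)} values for {n} years")
        if self.period_labels and len(self.period_labels) != n:
            raise DomainError("period_labels length mismatch")
        for s in self.s_trajectory:
            if not 0.0 <= s <= 1.0:
                raise DomainError(f"s={s} outside [0, 1]")
        for name in ("p_trajectory", "q_trajectory"):
            for v in getattr(self, name):
                if not 0.0 < v < 1.0:
                    raise DomainError(f"{name} value {v} outside (0, 1)")
        if set(self.n_implantations) != set(self.pregnancy_prob):
            raise DomainError("n_implantations and pregnancy_prob methods differ")
        for method, prob in self.pregnancy_prob.items():
            if not 0.0 < prob < 1.0:
                raise DomainError(f"pregnancy_prob[{method!r}]={prob} outside (0, 1)")
            if self.n_implantations[method] <= 0:
                raise DomainError(f"n_implantations[{method!r}] must be positive")

    def trajectory(self) -> list[TrajectoryPoint]:
        labels = self.period_labels or ("linear",) * len(self.years)
        return [
            TrajectoryPoint(year=y, s=s, p=p, q=q, period_label=lab)
            for y, s, p, q, lab in zip(
                self.years, self.s_trajectory, self.p_trajectory,
                self.q_trajectory, labels,
            )
        ]

    def to_dict(self) -> dict:
        return {
            "years": list(self.years),
            "n_implantations": dict(self.n_implantations),
            "pregnancy_prob": dict(self.pregnancy_prob),
            "s_trajectory": list(self.s_trajectory),
            "p_trajectory": list(self.p_trajectory),
            "q_trajectory": list(self.q_trajectory),
            "period_labels": list(self.period_labels),
            "noise": self.noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        required = {
            "years", "n_implantations", "pregnancy_prob",
            "s_trajectory", "p_trajectory", "q_trajectory",
        }
        missing = sorted(required - set(data))
        if missing:
            raise DomainError(f"scenario is missing field(s): {missing}")
        return cls(
            years=tuple(int(y) for y in data["years"]),
            n_implantations={str(k): int(v) for k, v in data["n_implantations"].items()},
            pregnancy_prob={str(k): float(v) for k, v in data["pregnancy_prob"].items()},
            s_trajectory=tuple(float(v) for v in data["s_trajectory"]),
            p_trajectory=tuple(float(v) for v in data["p_trajectory"]),
            q_trajectory=tuple(float(v) for v in data["q_trajectory"]),
            period_labels=tuple(str(v) for v in data.get("period_labels", ())),
            noise=bool(data.get("noise", True)),
            seed=int(data.get("seed", 0)),
        )


# Phase boundaries of the three-period trajectory, on the normalized SET-share
# axis u = (s - s_start)/(s_end - s_start); the q excursion sizes keep the
# mixture M(s) monotone decreasing (the rise in q must not outpace -(q-p)*ds).
_U_RISE_END = 0.3
_U_FALL_START = 0.7
_Q_RISE = 0.02
_Q_FALL = 0.02


def three_period_scenario(
    q_peak: float = 0.26,
    p_start: float = 0.025,
    p_end: float = 0.02,
    s_start: float = 0.05,
    s_end: float = 0.95,
    n_years: int = 15,
    cohort_size: int = 30_000,
    seed: int = 0,
    first_year: int = 1995,
    pregnancy_prob: float = 0.27,
    noise: bool = True,
) -> Scenario:
    """Reverse-sigmoid SET-uptake scenario realizing the three-phase curve.

    The SET share rises logistically from ``s_start`` to ``s_end`` over
    ``n_years``.  On the normalized share axis, ``q`` eases up to ``q_peak``
    over the first phase (improving ART success makes multi-embryo transfers
    likelier to implant more than one sac), holds through the middle phase, and
    eases down in the final phase; ``p`` declines linearly from ``p_start`` to
    ``p_end`` throughout.  The resulting M(s) curve is cap-shaped, then
    near-linear with slope about ``-(q - p)``, then cup-shaped.
    """
    if not (0.0 < p_end <= p_start < q_peak < 1.0):
        raise DomainError(
            f"require 0 < p_end <= p_start < q_peak < 1; "
            f"got p_end={p_end}, p_start={p_start}, q_peak={q_peak}"
        )
    if not (0.0 <= s_start < s_end <= 1.0):
        raise DomainError(f"require 0 <= s_start < s_end <= 1; got {s_start}, {s_end}")
    if n_years < 3:
        raise DomainError("n_years must be >= 3")

    t = np.linspace(0.0, 1.0, n_years)
    raw = 1.0 / (1.0 + np.exp(-8.0 * (t - 0.5)))
    u = (raw - raw[0]) / (raw[-1] - raw[0])  # normalized uptake, 0 -> 1
    s = s_start + (s_end - s_start) * u

    p = p_start + (p_end - p_start) * u

    q = np.full(n_years, q_peak)
    rising = u < _U_RISE_END
    q[rising] = q_peak - _Q_RISE * ((_U_RISE_END - u[rising]) / _U_RISE_END) ** 2
    falling = u > _U_FALL_START
    q[falling] = q_peak - _Q_FALL * ((u[falling] - _U_FALL_START) / (1.0 - _U_FALL_START)) ** 2

    labels = tuple(
        "convex-up" if ui < _U_RISE_END else ("linear" if ui <= _U_FALL_START else "convex-down")
        for ui in u
    )
    return Scenario(
        years=tuple(range(first_year, first_year + n_years)),
        n_implantations={"total": int(cohort_size)},
        pregnancy_prob={"total": float(pregnancy_prob)},
        s_trajectory=tuple(float(v) for v in s),
        p_trajectory=tuple(float(v) for v in p),
        q_trajectory=tuple(float(v) for v in q),
        period_labels=labels,
        noise=noise,
        seed=seed,
    )


def constant_scenario(
    p: float = 0.02,
    q: float = 0.26,
    s_values: Sequence[float] = (0.4, 0.5, 0.6, 0.7, 0.8),
    pregnancies_per_year: int = 10_000,
    pregnancy_prob: float = 0.27,
    noise: bool = True,
    seed: int = 0,
    first_year: int = 2005,
) -> Scenario:
    """Constant-(p, q) scenario: the identifiable regime of the linear reading.

    One synthetic "total" method; the SET share steps through ``s_values`` one
    year each; cohort sizes are set so the expected pregnancy count per year is
    ``pregnancies_per_year``.
    """
    n = len(s_values)
    return Scenario(
        years=tuple(range(first_year, first_year + n)),
        n_implantations={"total": int(round(pregnancies_per_year / pregnancy_prob))},
        pregnancy_prob={"total": float(pregnancy_prob)},
        s_trajectory=tuple(float(v) for v in s_values),
        p_trajectory=(float(p),) * n,
        q_trajectory=(float(q),) * n,
        period_labels=("linear",) * n,
        noise=noise,
        seed=seed,
    )


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def simulate_counts(scenario: Scenario) -> Cohort:
    """Draw one registry-shaped cohort from a scenario.

    With noise on, counts cascade binomially: pregnancies from implantations,
    SET pregnancies from pregnancies, SET multiples from SET pregnancies at p,
    non-SET multiples from the remainder at q; the multiple-pregnancy count is
    their sum, so count conservation holds by construction.  With noise off,
    each expectation is rounded half-even instead of drawn.  The same seed
    always yields the identical cohort.
    """
    rng = np.random.default_rng(scenario.seed)
    records = []
    for method in scenario.n_implantations:
        n_impl = scenario.n_implantations[method]
        prob = scenario.pregnancy_prob[method]
        for year, s, p, q in zip(
            scenario.years, scenario.s_trajectory,
            scenario.p_trajectory, scenario.q_trajectory,
        ):
            if scenario.noise:
                n_preg = int(rng.binomial(n_impl, prob))
                n_set = int(rng.binomial(n_preg, s))
                set_mult = int(rng.binomial(n_set, p))
                nonset_mult = int(rng.binomial(n_preg - n_set, q))
            else:
                n_preg = _round_half_even(n_impl * prob)
                n_set = _round_half_even(n_preg * s)
                set_mult = _round_half_even(n_set * p)
                nonset_mult = _round_half_even((n_preg - n_set) * q)
            records.append(
                CountRecord(
                    year=year,
                    method=method,
                    n_implantations=n_impl,
                    n_pregnancies=n_preg,
                    n_set_pregnancies=n_set,
                    n_multiple_pregnancies=set_mult + nonset_mult,
                    n_set_multiple_pregnancies=set_mult,
                )
            )
    return Cohort(tuple(records), label=f"synthetic(seed={scenario.seed})")


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate-level recovery of (q, q - p, p) from the linear reading.

    All values percent / percentage points.  ``generating`` entries are the
    scenario's true values (means over years, exact when constant)."""

    n_replicates: int
    q_hat: dict
    gap_hat: dict
    p_hat: dict

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "q_hat": self.q_hat,
            "gap_hat": self.gap_hat,
            "p_hat": self.p_hat,
        }


def _summarize(draws: np.ndarray, generating: float) -> dict:
    mean = float(np.mean(draws))
    return {
        "mean": mean,
        "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        "generating": generating,
        "bias": mean - generating,
    }


def recovery_experiment(
    scenario: Scenario, n_replicates: int, seed: Optional[int] = None,
    method: Optional[str] = None,
) -> RecoverySummary:
    """Repeat simulate -> rates -> linear fit -> mixture reading; summarize recovery.

    Replicate ``r`` simulates with seed ``seed + r`` (noise-off scenarios are
    deterministic, giving zero spread).  The linear reading's bias vanishes as
    cohort size grows only in the constant-(p, q) regime; under a moving q the
    line is a deliberate misspecification and the summary quantifies it.
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    if len(set(scenario.s_trajectory)) < 3:
        raise DomainError("scenario must span >= 3 distinct SET-share values")
    base_seed = scenario.seed if seed is None else seed
    method = method or next(iter(scenario.n_implantations))

    q_draws, gap_draws, p_draws = [], [], []
    for r in range(n_replicates):
        cohort = simulate_counts(replace(scenario, seed=base_seed + r))
        fit = fit_linear(regression_points(cohort, method))
        reading = interpret_linear_fit(fit)
        q_draws.append(reading.q_hat)
        gap_draws.append(reading.gap_hat)
        p_draws.append(reading.p_hat)

    gen_q = 100.0 * float(np.mean(scenario.q_trajectory))
    gen_p = 100.0 * float(np.mean(scenario.p_trajectory))
    return RecoverySummary(
        n_replicates=n_replicates,
        q_hat=_summarize(np.asarray(q_draws), gen_q),
        gap_hat=_summarize(np.asarray(gap_draws), gen_q - gen_p),
        p_hat=_summarize(np.asarray(p_draws), gen_p),
    )
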