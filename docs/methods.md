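# Methods

## Rate definitions

All rates are percentages derived from aggregate annual registry counts, per
calendar year and ART method group:

* **pregnancy rate per implantation** — pregnancies / transfer cycles.
  "Pregnancy" means an ultrasound-ascertained gestational sac; ectopic
  pregnancies are included.
* **SET pregnancy rate** (`X`, the observable counterpart of `100·s`) — SET
  pregnancies / all pregnancies.  Note this is the *share of pregnancies that
  followed SET*, not the per-transfer success rate of SET.
* **multiple pregnancy rate** (`Y = 100·M`) — multiple pregnancies / all
  pregnancies.
* **non-SET multiple pregnancy rate** (`100·q` up to sampling noise) —
  multiple pregnancies / (pregnancies − SET pregnancies); undefined and
  flagged when every pregnancy followed SET.

Rates are computed and carried at full floating precision.  Presentation
rounding (half-up, one decimal) exists only at the output boundary: fitting on
one-decimal rounded rates shifts the grand-total intercept by ≈0.13 and is not
what reproduces the published coefficients.

## The mixture model

`M = s·p + (1−s)·q = q − (q−p)·s`, with `s` the SET share of pregnancies, `p`
the multiple probability given a SET pregnancy and `q` given a non-SET
pregnancy.  All internal computation is on the fraction scale; conversion to
percent happens in the interpretation layer only.  This avoids double-percent
mistakes when relating a percent-on-percent slope (≈ −0.24) to the risk gap in
points (≈ 24): for a line `Y = b·X + a` on percent axes, `q̂ = a`,
`(q−p)̂ = −100·b`, `p̂ = a + 100·b`.

`p` after SET is (essentially) the monozygotic twinning probability.  `q`
after non-SET also contains some MZ twinning; the model does not and cannot
separate that portion, and no function here claims to.

## Trend fitting

Three functional forms of `Y` against `X`, both percent:

* **linear** — ordinary least squares, unweighted.  Registry method groups
  differ greatly in size, but the published coefficients correspond to
  unweighted OLS on the three yearly points, and with three points weighting
  is not meaningfully identifiable anyway.
* **quadratic** — least squares on the monomial design `(1, X, X²)`; with
  exactly three distinct-X points this is exact Lagrange interpolation
  (residuals at machine level, R² = 1).
* **exponential** — `Y = A·exp(B·X)` fitted as OLS of `ln Y` on `X`.  R² is
  reported on the log scale, where the least-squares problem actually lives
  (this matches the published values); the raw-scale R² is stored alongside.

Extrapolations `Y(X=100)` are always evaluated at full coefficient precision
and never clamped; a negative value is flagged as "form left its validity
region", not truncated.

### Which published cells reproduce exactly

Full-precision fitting reproduces the published linear rows (slope, intercept,
R²) for all four method groups, the grand-total exponential row, and the
linear extrapolation cells, at their printed rounding (three cells —
grand-total intercept 22.20, grand-total linear Y(100) −1.40, frozen linear
Y(100) −1.09 — sit within half a final-digit rounding unit of the
full-precision values 22.195, −1.394, −1.095 and are matched at ±0.01).

The published **quadratic** Y(100) cells and the **frozen exponential** one do
*not* equal full-precision evaluation: they are consistent with evaluating the
displayed formula after rounding the leading coefficient (at `X = 100` the
`X²` term amplifies a 0.0001 rounding of `a` by 10⁴).  `table2_report` marks
every extrapolation cell with a `y100_full_precision_reproducible` flag, and
the `report` command labels those cells "excluded" instead of comparing them.
This mixed-precision behaviour is documented, not emulated.

### Why the headline MZ estimate is the exponential form

At a 100% SET share the linear form goes negative (≈ −1.4 for the grand
total): the straight line is a local description of the middle uptake phase,
not of the endpoint.  The exponential stays positive and tracks the late-phase
flattening, landing at ≈ 2.3% for the grand total — consistent with direct
clinical observations of MZ twinning after SET (≈ 2%).  The flagged negative
linear value is retained as a lower bound.

The converse caveat matters for synthetic checks: on data that are *exactly*
linear (constant `p`, `q`), the convex exponential necessarily overshoots the
endpoint — fitting `exp(BX)` through a straight decline over `X ∈ [40, 80]`
and evaluating at 100 gives ≈ 4.6 rather than 2.  Its good performance on the
registry data comes from the real curve's curvature, not from any general
superiority; the test suite asserts exactly this asymmetry.

## Synthetic registry generator

`Scenario` holds per-year trajectories `(s, p, q)`, per-method cohort sizes
and pregnancy probabilities, a noise toggle and a seed.  `simulate_counts`
cascades binomials: pregnancies ~ B(implantations, pregnancy prob), SET
pregnancies ~ B(pregnancies, s), SET multiples ~ B(SET pregnancies, p),
non-SET multiples ~ B(remainder, q); the multiple-pregnancy count is their
sum, so count conservation holds by construction.  With noise off each
expectation is rounded half-even instead of drawn.  National registries
publish aggregates with no sampling model at all; the binomial mechanism is
this package's own assumption, the simplest count-valued one consistent with
the mixture.

`three_period_scenario` (defaults: `q_peak = 0.26`, `p` 0.025 → 0.020, `s`
0.05 → 0.95 logistically over 15 years, 30 000 implantations/year, pregnancy
probability 0.27) realizes the reverse-sigmoid contract.  On the normalized
uptake axis, `q` eases up by 0.02 over the first 30% (improving implantation
makes multi-embryo transfers likelier to yield two sacs), holds at its peak,
then eases down by 0.02 over the last 30%; `p` declines linearly throughout.
The excursion sizes are chosen so that the rise in `q` never outpaces
`−(q−p)·ds` — keeping `M(s)` strictly decreasing — while still producing
clearly cap-shaped, near-linear and cup-shaped phases (verified by second
divided differences of `M` against `s`: negative, |·| < 0.05, positive).  The
parametric forms themselves (logistic `s`, linear `p`, quadratic eases for
`q`) are artifact choices; only the monotonicity/convexity structure is part
of the modelled contract.

`constant_scenario` (defaults `p = 0.02`, `q = 0.26`, `s ∈ {0.4 … 0.8}`,
10 000 expected pregnancies/year) is the identifiable regime: there the linear
reading recovers `q`, `q − p` and `p` without bias, and
`recovery_experiment` (replicate `r` reseeded with `seed + r`) quantifies
spread, which shrinks as cohort size^(−1/2).  What passing these tests shows
is that the *estimator pipeline* is correct under its own assumptions; real
registries add non-binomial features (clinic-level correlation, reporting
changes, secular drift in `p` and `q`) that the generator deliberately does
not model.

## Numerical choices

* OLS via `numpy.linalg.lstsq` on explicit design matrices; independent
  normal-equations and Lagrange oracles in the tests agree to 1e-10.
* R² with zero total variance (constant response): defined as 1 when the
  residuals are at rounding level, else 0.
* Presentation rounding is decimal half-up (ties away from zero), matching
  registry tables; implemented with `decimal` to avoid binary-float tie
  surprises.
* Noise-off integerization rounds each expectation half-even; conservation
  needs no repair because the total multiple count is defined as the sum of
  its strata.

## Known limitations

* Three yearly points per method group: goodness of fit is descriptive, and no
  coefficient inference (standard errors, tests) is offered or meaningful.
* Multiple *birth* rates, triplet-vs-twin structure, maternal age, the
  elective/non-elective SET split and the MZ fraction of `q` are outside the
  data and the model.
* "Total" rows of the embedded cohort include small unpublished methods
  (e.g. GIFT), so they are stored as published, never recomputed by summing
  the printed groups; aggregate "subtotal" analyses are likewise not
  reproduced for lack of published counts.
* The frozen-transfer label covers the registry's intra-uterine frozen
  transfers; the correspondence is inferred from coefficient agreement and
  stated here rather than assumed silently elsewhere.
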