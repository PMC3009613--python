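# Methods

## Model structure and assumptions

The cohort model has four health states — acute LBP, chronic LBP, well,
dead — with quarterly cycles over a five-year horizon (20 cycles). The
entire cohort starts in acute LBP; the acute state is a one-cycle entry
state (there is no acute→acute transition), after which patients either
become chronic or recover. Recovered patients can relapse into chronic LBP;
death is absorbing and reachable from every living state at the same
age-indexed probability under both strategies (the treatment affects
recovery, not survival). The Markov assumption is taken as-is: chronicity
carries no memory of duration or severity (no tunnel states).

Clinical transition probabilities are per 3-month cycle and applied to the
surviving fraction 1−m of each state's occupancy, so every row of the
transition matrix sums to one by construction. Conversions between rates
and probabilities use the exponential identities p = 1 − exp(−r·t) and
r = −ln(1−p)/t throughout (including quarterly/annual mortality
conversion); probabilities are never divided or multiplied by time ratios
directly.

The treatment effect enters in two places: the chronic→well probability is
multiplied by the recovery risk ratio RR (capped at 1, with a logged
warning when a PSA draw would exceed it), and the chronic-state utility is
strategy-specific (0.65 vs 0.62). An alternative rate-scale application of
the RR (multiplying the instantaneous recovery rate, i.e.
p′ = 1 − (1−p)^RR, which never needs capping) is available via
`conventions.rr_scale: rate`; the default is the multiplicative
probability-scale reading, which matches the published transition matrix.

## Parameters

| name | meaning | point value | PSA distribution |
|---|---|---|---|
| tATC | acute→chronic / cycle | 0.24 | Beta(29, 91) |
| tWTC | well→chronic / cycle | 0.16 | Beta(26, 137) |
| tCTW | chronic→well / cycle (usual care) | 0.35 | Beta(135, 252) |
| tRR  | recovery risk ratio | 1.40 | lognormal(0.34, 0.05) |
| uALBP / uCLBPUC / uCLBPACUC / uWell | state utilities | 0.85 / 0.62 / 0.65 / 0.96 | Beta |
| cUC / cACUC | chronic-state cost / cycle, KRW | 507,776 / 730,329 | Gamma |
| — | mortality / cycle | 0.001 | fixed schedule |
| — | annual discount rate | 0.05 | fixed |

Complement pairs (tATC, tATW) and (tWTC, tWTW) are sampled as one Beta draw
plus its complement, preserving row-stochasticity in every draw. Draw order
within an iteration is fixed (transitions, utilities, costs, risk ratio),
so a seed fully determines the sequence. `check_distribution_consistency`
verifies at run time that every distribution's analytic mean matches its
point value within 2% — the parameterizations above reproduce all printed
point values (worst gap 0.7%). The chronic utilities are sampled
independently, so a draw may order them "wrongly" (collaboration below
usual care); this is deliberate and contributes honest decision
uncertainty at low thresholds.

Costs: the per-cycle chronic-state cost is the sum of a per-visit
reimbursement schedule (one first visit, six diagnosis-and-treatment
visits, three treatment-only visits per quarter) and a direct non-medical
component. The indirect productivity cost (239,142 KRW/cycle, equal for
both strategies, from wage × economically-active share × employment rate ×
lost days) is excluded in the base case and toggled on for the univariate
sensitivity analysis; because it is equal per cycle, it changes the
incremental cost only through the strategies' different chronic occupancy,
shrinking ΔCost and the ICER.

## Reward and discounting conventions

Spreadsheet-era cohort models are rarely explicit about when rewards
accrue, and the published headline totals here cannot be reproduced under
every convention. The package therefore exposes the choices explicitly:

- `reward_timing: start|end` — whether occupancy at the start of each of
  the 20 cycles (cycle 0 = the all-acute entry cycle) or after each
  transition earns that cycle's cost and QALYs. Default: `start`.
- `half_cycle: on|off` — trapezoidal occupancy. Default: off.
- `outcome_discounting: per_cycle|none` — whether accumulated outcomes are
  discounted at (1+r)^(−cycle·0.25) per cycle. Default in the shipped
  configuration: `none`.

The last default deserves a plain statement. Discounting the quarterly
rewards at the stated 5% annual rate yields per-person totals roughly 8%
below the published ones (≈3.79 vs 4.11 QALYs for usual care), under every
timing/half-cycle combination, while the *undiscounted* accumulation
reproduces all five headline numbers — both QALY totals, both cost totals,
and the ICER — within about 3%. The ICER itself is nearly insensitive to
the choice (both deltas scale together). The shipped configuration
therefore accumulates undiscounted totals as the headline outcome so that
its defaults reproduce the published base case; both variants are always
computed and reported on every `StrategyOutcome`, and `per_cycle` is a
one-line config change. Agreement within ±5% rather than to the printed
digit is the honest expectation, because the original life-table values
and accrual convention are not recoverable.

Mortality: the published model used national life tables whose values are
not printed. The default configuration uses a constant 0.001 per quarterly
cycle (annual ≈ 0.4%, plausible for a 60-year-old Korean woman in 2009);
the synthetic life-table generator (below) provides an age-increasing
alternative via `mortality.kind: life_table`. This stand-in is the main
known source of residual discrepancy in absolute costs/QALYs.

## Sensitivity, acceptability and value of information

The PSA redraws all parameters jointly (10,000 iterations by default),
evaluates both strategies on each shared draw, and records per-strategy
and incremental outcomes. The CEAC uses the pairwise definition: the
probability that collaboration's net monetary benefit strictly exceeds
usual care's, ties counted toward the reference, so the two curves sum to
one exactly. (The published curve's two probabilities at the 20M threshold
sum to 98.6%, indicating some other, unrecoverable computation; the
pairwise probability lands within a couple of percentage points of it.)
The 50% crossing is reported both as the first grid threshold reaching the
level and as a linear interpolation. The λ grid spans 0–20,000,000 KRW per
QALY in 20,000 steps.

EVPI per person is E[max NMB] − max E[NMB] over the draws; population
EVPI multiplies by the discounted incident population
Σₜ 57,400/(1.05)^t, t = 0..4 (annual cohorts arriving at the start of each
of five years, year 0 undiscounted; `cohort_timing: end` discounts every
cohort one extra year). The resulting curve shows a local maximum near
λ ≈ 4M KRW — the region where the adoption decision actually flips — and
rises again at high λ where QALY-side uncertainty dominates.

## Meta-analysis

Study-level 2×2 recovery counts are pooled on the log risk-ratio scale
with the DerSimonian–Laird moment estimator (Cochran's Q, τ² truncated at
zero, inverse-variance weights 1/(se²+τ²)). A 0.5 continuity correction is
added to all four cells only when a study has a zero-event arm; studies
with zero events in both arms are dropped as non-informative. The pooled
(logRR, se) maps directly onto the PSA's lognormal risk-ratio
distribution; exp(0.34) ≈ 1.40 reproduces the model's point value. The
source trials' counts are not printed anywhere machine-readable, so the
default pipeline uses the pooled lognormal(0.34, 0.05) directly, and the
pooling stage runs on user CSVs or on the synthetic evidence base. The
implementation is cross-checked in the tests against two independent
references: frozen results from R's `metafor` (method="DL") and
`statsmodels.stats.meta_analysis.combine_effects` (heterogeneous data
only, since statsmodels does not truncate τ² at zero).

## Synthetic data

Two generators stand in for unavailable external inputs; both are
seed-reproducible and clearly labelled synthetic.

*Evidence base*: each synthetic trial draws its own log risk ratio from
Normal(0.34, 0.1²), an arm size uniform on 100–300 (defaults; the
parameter-recovery tests use 50 trials of 200–500), and binomial recovery
counts at a 35% baseline. This emulates the statistical structure the
pooling assumes — exchangeable normally distributed study effects around a
common mean — and nothing else: no publication bias, no differing outcome
definitions, no arm imbalance. Passing recovery tests show the estimator
works under its own assumptions, not that the published evidence satisfies
them.

*Life table*: annual mortality q(a) = 0.004·(1.08)^(a−60) for five years
from age 60 — a Gompertz-like schedule with a plausible level and slope,
not a fit to any national table — converted to quarterly probabilities
through the rate identities so four quarters recompose the annual value
exactly.

## Numerical choices and edge cases

- All internal arithmetic is double precision; KRW are rounded only for
  display. The ICER uses full-precision deltas (the published ΔQALY of
  0.13 is a rounding of ≈0.134; dividing the printed numbers does not
  reproduce the printed ICER, the full-precision ratio does).
- Trace conservation is enforced to 1e-10 in tests; the cohort engine is
  verified against explicit path enumeration (≤4 cycles, 1e-12) and
  matrix powers.
- Degenerate inputs: zero-variance ("fixed") distributions collapse the
  PSA to the deterministic base case exactly, the CEAC to a step at the
  ICER, and the EVPI to zero (to float roundoff, ~1e-6 KRW on 1e8-KRW
  magnitudes).
- ICER edge cases return labels, not crashes: "equivalent", "dominant",
  "dominated", "infinite" (equal effects, different costs). The
  n-strategy table additionally prunes extended dominance.
- RR×tCTW > 1 draws are clamped to 1 and logged, never dropped — dropping
  would bias the PSA.

## Problem sizes

The shipped analyses use the full configuration: 20-cycle deterministic
runs (milliseconds), 10,000-draw PSA (~1 s), 1,001-point CEAC and EVPI
grids. The test suite uses 2,000-draw PSA fixtures for the stochastic
property tests and the full 10,000 draws for the headline acceptability
checks.

## Known limitations

- The mortality stand-in and accrual-convention ambiguity bound agreement
  with the published absolute totals at the few-percent level (the
  incremental results are robust to both).
- No tunnel states, no duration-dependent chronicity, no treatment effect
  on mortality, no acute-state costs — all by design of the original
  model.
- The CEAC definition ambiguity above; the published figure-derived EVPI
  magnitudes are treated qualitatively, not as targets.
- Utilities, costs and transition probabilities are sampled independently
  (apart from the enforced complements); no correlation structure is
  available in the source material.
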