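# Methods

`bcfollow` estimates the budget impact and financial risk of extending the
publicly financed follow-up of breast-cancer patients beyond the five
monitoring years the Mexican catastrophic-expenditure fund (FPGC) covers
after a one-year treatment. The pipeline has five modelling stages plus a
synthetic-input generator; this note records the model, its assumptions, the
parameters that matter, and the design choices that were genuinely open.

## Cohort model

**Incidence.** The average age-specific incidence is estimated from
registry counts as the mean over historical years *k* = 2007…2013 of the
cell-wise ratios of new cases to the at-risk population,

    Io_e = (1/n) Σ_k Cn_{k,e} / Pr_{k,e},    e = 0…100.

Cells with a zero denominator and zero numerator contribute a zero ratio
(keeping *n* constant per age); a zero denominator with positive cases is
rejected. Incidence is held constant over the projection horizon — no
secular trend is modelled — so all projected growth comes from demographic
change. Incidence is applied from age 20 upward only; younger ages carry
rate 0.

**Susceptible population and projection.** The susceptible population is
the projected female population times the reference-year (2013) affiliation
share by age, `Ps_{i,e} = PC_{i,e} · PA_{2013,e}`. Expected served cases
are `C_{i,e} = Io_e · Ps_{i,e} + Σ_j Cs_{j,e}`, where `Cs` are the cohorts
diagnosed in 2007–2012 and still monitored at 2013, carried forward by
aging (one year of age per calendar year; the open age-100 bin absorbs the
oldest). The typeset form of the projection equation in the source
literature places the prior cohorts inside the incidence bracket,
`C = Io·(Ps + ΣCs)`; that reading multiplies a patient stock by an
incidence rate and contradicts the surrounding accounting (prevalence =
new cases + monitored prior cases), so the additive form is the default
and the literal form is available behind `literal_bracket=True`.

**Survival and the cycle table.** One age-specific case-fatality schedule

    L_e = (1/n) Σ_k M_{k,e} / D_{k,e}

is applied to all stages (the registry does not link stage to outcome).
Each diagnosis cohort is depleted annually from the diagnosis year onward,
`S = C(1 − L_age)`, with every patient aging one year per cycle — per-age
bookkeeping, not a scalar rate. A cohort diagnosed in year *d* enters the
extended-monitoring caseload after the financed window of 1 treatment year
+ 5 monitoring years and stays in it, further depleted, through the end of
the reporting horizon; no cure or exit is modelled, which produces the
10-to-23-year coverage asymmetry across the 14 cohorts (2013–2026).

*Column labelling.* The cycle table's columns are diagnosis-aligned: the
column labelled `c` holds every cohort's survivor count realized in
calendar year `c + 6`, so cycle 1 (the 2013 cohort) shows its entry count
(realized 2019) in the 2013 column, totals rise while cohorts enter
(through 2026) and decline afterwards, and the costing years 2013–2026
align with the published accounting. The realized-calendar labelling of
the same columns is exposed via `calendar_years` / `to_csv(labeling=
"entry")`; the choice between the two is a presentation question the
source table leaves ambiguous, so both are provided.

## Micro-costing

The per-patient-year monitoring cost is the sum of its components
(medicines + clinical analyses) inflated 3% annually from 2013:
`Ks_i = (M0 + AC0)(1.03)^(i−2013)`. Components are inflated as a sum; at
a common rate the result is identical to inflating them separately. The
itemized price lists behind the components are not public; the default
total of 18,000 pesos/patient-year is the scale anchor implied by dividing
the published cumulative extension cost by the ≈200,000 monitored
person-years. Annual cost is `C_i = Cs_i · Ks_i`; money is carried in
pesos internally and reported in million pesos, rounded half-up to two
decimals only at the reporting boundary (percentages to one decimal).

## Monte-Carlo maximum expected cost

Cost uncertainty is modelled by a lognormal stochastic process

    C_i = C0 · exp[(μ − σ²/2)Δ_i + σ W_Δi],   W_Δ = Σ_{t≤Δ} η_t,  η_t ~ N(0,1),

whose marginal at elapsed time Δ equals the standard lognormal
`C0·exp((μ−σ²/2)Δ + σ√Δ·ξ)`. Using a cumulative Brownian path rather than
independent per-year draws makes year-over-year log ratios i.i.d.
N(μ−σ²/2, σ²), so `estimate_lognormal_params` (σ = sd of log ratios,
μ = mean + σ²/2) is consistent and exactly recovers μ on deterministic
paths. The fitted (μ, σ) of the original analysis were never published;
the defaults are μ = 0 (drift is already carried by the 3% cost inflation,
so a nonzero μ would double-count it) and σ = 0.10 per √year, a moderate
cost volatility chosen once. Both are configuration keys.

Each iteration draws one multiplier per risk factor (incidence, fatality,
cost) and a cost path, reruns the projection→cycles→costing chain (the
incidence multiplier acts linearly on the new-case component, so the
unshocked decomposition caseload = prior + m·new is exact; fatality shocks,
off by default, trigger a full cycle-recursion rerun), and records the
cumulative 2013–2026 cost. The *maximum expected cost* is the right-tail
cut-off V_c with `P[cost > V_c] ≤ α`: the nearest-rank ⌈(1−α)n⌉-th order
statistic at α = 0.05, n = 5000. Nearest-rank was chosen over interpolated
quantiles for its reproducible integer rule. The printed form of the
tail-probability equation would make V_c a *low* quantile
(`P[c ≥ V_c] = 1 − α`); the stated intent — only 5 of 100 iterations may
exceed the cut-off — dictates the 95th percentile, which is what is
implemented. V_c is computed on the cumulative cost (the published
headline amounts are cumulative); per-year V_c profiles are also exposed.

**Scenarios.** Base: all multipliers at 1. Pessimistic/optimistic:
incidence and cost multipliers from a truncated lognormal with median
1.05 / 0.95 restricted to [1.00, 1.10] / [0.90, 1.00] — honouring both
the lognormal risk-factor family and the stated "up to 10%" range; a
uniform option exists. Fatality multipliers default to a point mass at 1
(the scenario narrative varies only incidence and costs) and can be
enabled. All scenarios share one seed and draw through inverse-CDF
coupling (common random numbers), which guarantees the per-iteration
ordering optimistic ≤ base ≤ pessimistic and hence ordered V_c. Each
iteration uses a deterministic `SeedSequence` substream, so results are
independent of execution order.

## Fund reporting

End-of-year fund availability is opening availability + contributions −
commitments; the published 2007–2013 ledger ships as data-as-given,
including its own 0.30-million discrepancy between end-2012 (4487.70) and
opening-2013 (4487.40). V_c is amortized over 18 years — three 6-year
federal administrations, the stated policy horizon — even though the
cycle table spans 14 entry cohorts; 18 is the divisor that reproduces the
published annual amounts (e.g. 3607.40/18 = 200.41). The availability
share uses *end-of-2013* availability (6743.50) as denominator:
200.41/6743.50 → 3.0%, matching the published figure, whereas the opening
balance does not. The published text swaps the pessimistic/optimistic
share labels relative to its own amounts (230.66/6743.50 = 3.4% is the
pessimistic, not optimistic, share); the package reports computed values.

## Synthetic data generator

The generator emulates the statistical structure of the registry inputs,
which were never deposited:

- **Age pyramid:** flat to age 45, piecewise-linear decline to a 4% floor
  at 100 — a smooth stand-in for the official projection; only the product
  incidence × pyramid matters downstream. Population grows 1.0%/year with
  a static age structure; the affiliation share is a flat 0.45.
- **Incidence shape:** logistic rise (midpoint 42, scale 3) × plateau to
  66 × gaussian decline (sd 11), zero below age 20, scaled so the 2013
  affiliated population yields 7841 expected diagnoses. The implied case
  distribution puts 54.8% of cases at ages 50–69 and 92.5% at 40–79.
- **Fatality shape:** exactly 18.7 per 100,000 diagnosed at ages 20–29,
  sigmoid rise (midpoint 55, scale 7) to a 32,000 per 100,000 old-age
  plateau. The plateau is calibrated so a diagnosis cohort retains ≈32%
  of its members after the six financed years, consistent with the
  reported cycle-1 survival (2531 of 7841). The published per-age curves
  print no values except the 18.7 floor, so the schedules are
  shape-calibrated, not value-calibrated.
- **Counts:** at-risk cells are deterministic; new cases are Poisson
  around incidence × at-risk, except 2013 which is multinomial so the
  cohort totals exactly 7841; diagnosed = new cases; deaths are
  Binomial(diagnosed, fatality), enforcing deaths ≤ diagnosed cell-wise.
- **Stage mix:** 28/61/9 renormalized to sum to 1 (the printed shares sum
  to 98); purely descriptive — one monitoring cost applies to all stages.

What the generator does **not** emulate: incidence trends, cohort-specific
fatality improvement, stage-specific costs or outcomes, migration, age
structure change, and reporting artifacts of real registries. Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery under the stated conditions, not agreement with any real
registry; in particular the headline peso amounts depend on unpublished
per-age inputs and are expected to differ in scale from the published
ones (the synthetic caseload includes the surviving 2007–2012 cohorts in
every column, ≈240,000 person-years against the published 200,410).

## Numerical choices and degenerate inputs

- Multi-year survival uses an iterated-product table `G[a, m]`; fatality
  beyond age 100 is held at the age-100 value. Flat-rate inputs reduce it
  to `(1−q)^m` to machine precision.
- Zero at-risk (resp. diagnosed) cells with zero numerators contribute
  zero ratios; with positive numerators they raise errors.
- Zero incidence reduces the projection exactly to the aged prior stock;
  zero fatality makes survivors equal cases.
- A fatality fraction of 1 empties a cohort in one cycle.
- Fewer than 20 expected tail iterations (α·n < 20) triggers a warning
  that the quantile error of V_c is large.
- Problem sizes: the default study conditions (101 ages × 24 projection
  years, 14 + 6 cohorts, 3 × 5000 iterations) run in a few seconds; the
  test suite uses reduced Monte-Carlo budgets (50–1000 iterations) where
  only the machinery, not the tail accuracy, is under test.

## Known limitations

- The caseload includes prior (2007–2012) cohorts from the first column
  on, as the accounting prescribes; the published cycle table starts its
  first column with cycle 1 only, so its totals are not directly
  comparable to the synthetic ones.
- Relapse financing (relapses re-enter as new treatment cases) is out of
  scope, as is any stage-specific costing and the fund's portfolio risk
  across other covered diseases.
- The 9.1% share of annual breast-cancer expenditure is not reproduced:
  its denominator was never published.
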