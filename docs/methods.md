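# Methods

## Cohort model

A closed cohort (no entries after baseline) is followed over `[0, T]`
weeks. Each individual is unexposed or exposed; exposure is absorbing
(one-way migration, as with vaccination or infection) and the outcome
removes an individual from risk. Time is partitioned into intervals on
which three quantities are constant:

* `R0` — outcome hazard in the unexposed, events per person-week;
* `HR` — exposed:unexposed hazard ratio, so the exposed hazard is
  `R1 = HR · R0`;
* `E` — new-exposure (migration) rate, per person-week.

The expected compartment masses `x = N·P0` (unexposed) and `y = N·P1`
(exposed) then obey the linear system `x' = -(R0+E)x`,
`y' = -R1·y + E·x` with piecewise-constant coefficients. Note the
migration inflow to the exposed compartment is proportional to the
*unexposed* mass `E·x`: each migrant leaves one compartment and enters
the other, so total mass declines only through outcome events. An
update with inflow proportional to the exposed mass would create or
destroy migrants and distorts the prevalence trajectory noticeably at
these rates; the conserving form is used throughout.

## Numerical scheme

The integrator advances the state by an explicit (Euler) update on a
uniform subgrid of each interval,

```
x(t+Δ) = x(t)·(1 − R0Δ − EΔ)
y(t+Δ) = y(t)·(1 − R1Δ) + EΔ·x(t)
```

and accumulates all integrals (expected cases `A_i`, density controls
`B_i`, person-time `PT_i`, discordant-pair masses `M_ij`) as
left-Riemann sums on the same grid. The default resolution is 1000
subintervals per week; interval boundaries always coincide with grid
points (an interval whose length is not a multiple of the spacing uses
the nearest spacing that divides it exactly). Steps that could remove
more than a compartment's whole mass — `(R0+E)Δ ≥ 1` or `R1Δ ≥ 1` —
raise an error rather than silently going negative.

The scheme is first-order: the relative gap to the exact
piecewise-exponential solution is ≈ `λ²·t·Δ/2` with `λ` the total
outflow rate of a compartment. At the default resolution this is below
1e-5 for weekly rates of a few percent and ~1.5e-4 for the most
aggressive preset interval (`E = 0.5/week`). Doubling the resolution
moves every reported estimand by less than 1e-4 relative (verified in
the acceptance suite). An exact exponential stepper would be trivially
available but the explicit scheme is retained deliberately: the
estimands are defined via the same left-Riemann construction, and
exactness is delegated to the test oracles (closed-form compartment
solution; adaptive quadrature on it for the integrals).

## Estimands

With `a_i = N·P_i·R_i` and `b_i = (a0+a1)·P_i`,

* **rate ratio** `= [A1(T)/PT1] / [A0(T)/PT0]` — the person-time
  outcome-rate ratio of the source cohort;
* **matched OR** `= M10/M01` with `M_ij = ∫ a_i(t)·P_j(t) dt` — the
  large-sample limit of the Mantel–Haenszel (discordant-pair) OR under
  1:m risk-set sampling. The ratio of expected exposure-discordant pair
  masses is used; concordant pairs carry no information and the
  control:case ratio m cancels;
* **unmatched OR** `= A1·B0/(A0·B1)` — the limit of the crude OR when
  density controls are pooled without time stratification;
* **final proportion unexposed** `= x(T)/(x(T)+y(T))` — a one-number
  summary of how much exposure prevalence moved.

Two identities follow directly and serve as invariant tests. For
constant `HR = h`: `a1·P0 / (a0·P1) = R1·y·x / (R0·x·y) = h` pointwise,
so matched OR `= h` exactly, and the same cancellation gives rate
ratio `= h`; both hold for any baseline hazard, uptake pattern and
initial prevalence (grid-exact, not merely O(Δ)). If additionally the
prevalence `P1(t)` is constant, `B_i ∝ A_+·P_i` makes the unmatched OR
collapse onto the same value; when prevalence changes, the unmatched
OR is biased toward the null, and it always satisfies
`|log OR_u| ≤ |log h|`.

Population ORs and risk ratios over the whole period are deliberately
not computed for migration scenarios: with time-varying exposure the
cohort cannot be cross-classified by a single exposure value, and the
closed-cohort 2×2 (`contingency` module) is restricted to
fixed-exposure scenarios.

## Preset family and calibration

The twelve presets cross four hazard-ratio profiles (constant 0.4,
constant 2.5, waning 0.8/0.4/0.2, increasing 1.25/2.5/5.0) with three
uptake profiles (none, pulsed 0.1/0.5/0.1, steady 0.1) over three
one-week intervals. The baseline hazard (0.025/week) and initial
unexposed proportion (0.8) are free parameters of the family, chosen
once so that the final-prevalence trajectories span roughly 0.4–0.8 —
an epidemiologically plausible regime in which exposure uptake moves
prevalence substantially but the outcome stays uncommon (cumulative
incidence ≈ 7% per 3 weeks in the unexposed). The constant-HR
identities are invariant to this calibration; the unmatched OR and the
varying-HR rate ratios depend on it only weakly (second decimal).

## Monte Carlo simulator

`simulate_cohort` realizes the stochastic process whose expectations
the integrator computes. Each individual starts unexposed with
probability `P0(0)`; while unexposed and event-free it faces competing
piecewise-exponential risks of switching (rate `E`) and of the outcome
(rate `R0`); after switching, the outcome hazard is `R1`. Event times
are drawn by inverse-CDF inversion of the piecewise-linear cumulative
hazard, vectorized over the cohort; the exposed-phase clock starts at
the (individual-specific) switch time. Competing risks are realized as
the minimum of independent draws, which is distributionally exact for
hazard-additive competing risks; exact ties (probability zero in
continuous time) resolve in favour of the outcome. All draws come from
numpy `Generator`s spawned off a single `SeedSequence`, one stream per
draw stage, so results are reproducible from one integer seed and
independent of any iteration order.

Control sampling implements four designs. In `risk_set` sampling each
case at time t is matched to m controls drawn uniformly without
replacement from everyone still event-free at t — future cases are
eligible, one person may serve several cases, and exposure is recorded
as of t (these are exactly the conditions under which the matched
estimand theory holds). `unmatched_density` reuses the same mechanics
but discards the matching. `cumulative` draws controls from those
event-free at T, and `case_cohort` from the whole baseline cohort;
both treat exposure as a fixed attribute and therefore refuse
scenarios with migration (an explicit `UnsupportedDesignError`, not a
silent reinterpretation). Samples are analysed with the
Mantel–Haenszel OR over matched sets (which for 1:1 matching reduces
to the discordant-pair ratio) or the crude pooled OR; no logistic
models are fitted — the questions here concern estimands, and the MH
estimator suffices for convergence checks.

`convergence_report` replicates the whole pipeline, shares each
simulated cohort across designs within a replicate, and reports the
mean and standard error of the log sample OR together with the
deterministic target of each design and the z-score of the gap. The
design-separation acceptance check uses cohorts of n = 200 000 with 20
replicates (≈ 11 000 cases each), which makes the 0.40 vs 0.43 gap of
the pulsed-uptake preset resolvable at > 3 combined standard errors in
a few seconds of CPU time.

## Numerical and degenerate-input policy

No continuity corrections anywhere: zero cells, zero person-time,
extinct cohorts and all-concordant matched samples raise descriptive
`DomainError`s, because the package computes population parameters and
their large-sample limits, not small-sample estimates. Scenario
validation errors name the offending field. Displayed tables round
half-even to 2 decimals; CSV/JSON outputs keep full precision.

## Limitations

* The generator emulates idealized conditions: no censoring other than
  the outcome, no competing risks, no measurement error, no selection
  bias, perfect case ascertainment. Passing tests show the estimators
  converge to their design targets under these conditions; they say
  nothing about confounding or data-quality problems in real studies.
* Exposure migration is one-way and exposure is binary.
* The explicit integrator is first-order; users probing regimes with
  per-week rates approaching 1 should raise `steps_per_week`.
* Variance formulas are limited to the empirical SE of the log OR
  across replicates; no confidence intervals are produced.
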