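# Methods

## Model and assumptions

The package implements a deterministic break-even (cost-neutrality)
analysis. Over `S` annual surgeries, universal prophylaxis costs
`C_d · S` (course price plus monitoring add-on, per patient) and the VTE
treatment bill falls from `C_t · VR_i · S` to `C_t · VR_f · S`. Setting the
saving equal to the spend and solving for the final rate gives

    VR_f = (C_t · VR_i · S − C_d · S) / (C_t · S) = VR_i − C_d / C_t,

so the result is independent of surgical volume; `break_even_rate`
nevertheless evaluates the literal volume-carrying form alongside the
reduced form and raises if they disagree beyond 1e−12, which doubles as a
continuous self-check of the cancellation. `ARR = C_d / C_t` is the risk
reduction the drug must deliver to pay for itself and `NNT = 1/ARR` the
courses bought per event that must be prevented.

Assumptions inherited from the model class: every patient receives the
course (no partial uptake), drug and treatment costs are flat per-unit
scalars (no discounting, no QALYs, no bleeding-complication costs), and
efficacy is deliberately *not* modelled — outputs are required reductions,
not predicted ones. These are break-even semantics: the model marks the
line a drug must beat, nothing more.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `course_cost` | 1-month prophylactic course, retail | per drug ($0.30–$504.23) | USD |
| `monitoring_cost` | add-on per course (INR testing) | 0; $6.19 for monitored warfarin | USD |
| `treatment_cost` (`C_t`) | cost of treating one symptomatic VTE | $9407 (institutional estimate) | USD |
| `initial_rate` (`VR_i`) | baseline symptomatic VTE rate | 0.0046 / 0.0101 / 0.098 | fraction |
| `annual_surgeries` (`S`) | annual TAA volume | 1 (cancels) | count |
| `alpha`, `power` | sample-size calculator | 0.05 two-sided, 0.80 | — |

Rates are decimal fractions everywhere inside the package; percent values
exist only at I/O and formatting boundaries. Currency is exact
`decimal.Decimal` dollars on the domain types and in all file I/O, so
prices like $138.77 round-trip without binary-float contamination; floats
appear only inside the arithmetic.

## Numerical and formatting choices

- **Rounding** is half-away-from-zero at every display boundary
  (`round_half_away`, via `decimal`), including integer NNT. This is the
  convention the published escalation table implies (50000/138.77 = 360.31
  prints 360, where ceiling would give 361; 110000/504.23 = 218.15 prints
  218).
- **Cost-effectiveness boundary**: a final rate of exactly zero counts as
  cost-effective, implemented as `final_rate ≥ −1e−12`. The tolerance
  absorbs the float round trip `C_d / (C_d / VR_i)` at the threshold
  treatment cost and is ~9 orders of magnitude below one cent of
  treatment-cost resolution at the package's price scales.
- **Negative final rates are reported as-is**, never clamped: they are the
  infeasibility signal (the drug would need to prevent more events than
  occur).
- **Monitoring cost is additive** wherever `C_d` appears; the monitored
  warfarin scenario is $2.10 + $6.19 = $8.29, which is the only reading
  that reproduces its published NNT of 1135 = round(9407/8.29).
- **Sweep contracts**: axis grids must be strictly increasing (callers
  sort; silent sorting would hide data errors). Along a treatment-cost
  grid, ARR strictly decreases and exact NNT strictly increases — checked
  by tests as monotonicity invariants.
- **Sample size** uses the pooled-variance normal approximation for two
  independent proportions, two-sided α, no continuity correction, equal
  allocation, per-arm ceiling. This is the most common textbook convention;
  the operation's contract is the formula itself. At ARRs around 0.003% it
  yields totals in the 10⁸ range — the model's argument for why the
  equivalent trial cannot be run.

## Reference tables and documented anomalies

The packaged reference CSVs hold the published sensitivity cells as printed
strings with their per-cell decimal places, alongside parsed numerics. The
published drug × initial-rate table mixes precision (aspirin 81 at 3 dp,
the rest at 2 dp) and its 1.01% column is internally inconsistent with the
model's own arithmetic under any single rounding convention: five of its
six final-rate cells ("1.017", "1.00", "−0.46", "−4.34", "1.00") cannot be
regenerated from `VR_i = 1.01%` exactly (some match the unrounded
16/1577 = 1.014584% instead, some match neither). These cells carry
`final_rate_excluded = 1`: they remain visible as documented anomalies and
tests assert that the model's value *differs* from them, never that it
matches. Every ARR and NNT cell, the whole 0.46% and 9.8% columns, and the
complete treatment-cost escalation table regenerate exactly. The
abstract-level "0.0003%" ARR for aspirin 81 is likewise treated as a typo
for 0.003% (0.30/9407 = 0.0032%) and never asserted.

## The synthetic cohort

`generate_cohort` emulates the *structure* of the registry extract the
incidence estimate came from — per-patient prophylaxis flag and a VTE
within a 28-day window — not the registry itself, which is
access-restricted. Defaults mirror the reported extract: cohort size 3455,
prophylaxis fraction 1878/3455 ≈ 0.543, untreated-arm true rate 1.01%.
Patients are i.i.d. Bernoulli in both dimensions; the treated-arm rate is a
free parameter carrying no efficacy claim. The ICD-10/CPT codes of the
original query are carried as documentation-only metadata
(`REGISTRY_QUERY_METADATA`). Deliberately **not** emulated: demographic
covariates and confounding, drug-level assignment within the prophylaxis
arm, coding error and under-ascertainment, and time-to-event structure.
Passing recovery tests therefore show that the estimator is correct for an
idealised binomial registry, not that the registry's own rate is unbiased —
the original analysis itself notes that claims-code queries miss
asymptomatic and unrecorded events.

Incidence intervals use the Wilson score interval by default (well-behaved
at 16 events in 1577), with exact Clopper–Pearson as an option; both come
from `statsmodels`, and tests cross-check Wilson against an independent
beta-quantile Clopper–Pearson computation.

## Problem sizes

The parameter-recovery check runs 500 seeded cohorts of 20,000 patients
(mean recovered rate within 3 Monte-Carlo standard errors of truth,
~16 s on one CPU); the equation-level property checks use 10,000 random
(C_d, C_t, VR_i, S) instances; `scripts/acceptance.py` averages 200 seeded
cohorts for its recovered-rate entry. These sizes put the Monte-Carlo
error of the recovery checks near 3 × 10⁻⁵ on a 1.01 × 10⁻² rate while
keeping the whole suite around half a minute.

## Known limitations

- One-way sensitivity only, matching the published analysis; no
  probabilistic sensitivity analysis or two-way grids.
- The break-even verdict is binary and ignores partial uptake, adherence,
  bleeding harms and indirect costs; thresholds should be read as lower
  bounds on the economic bar, not as recommendations.
- The sample-size formula is one of several conventions (arcsine,
  continuity-corrected and Fisher-exact-powered variants differ by a few
  percent); it is provided to show order of magnitude, not for trial
  design.
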