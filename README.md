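# vtecost

Break-even cost-effectiveness modelling of venous-thromboembolism (VTE)
chemoprophylaxis after total ankle arthroplasty (TAA).

Symptomatic VTE (deep venous thrombosis or pulmonary embolism) after TAA is
uncommon — reported rates run from 0.46% to 9.8%, with a federated EHR
registry giving 16/1577 = 1.01% among patients who received no
chemoprophylaxis — but each treated event is expensive (about $9407 at the
institution the model's default uses). Prophylactic drugs, meanwhile, range
from $0.30 to over $500 for a 1-month course. Because trials large enough to
measure efficacy at these event rates are infeasible, `vtecost` implements a
break-even analysis: it computes the risk reduction a drug would *have* to
deliver to pay for itself, leaving the question of whether it actually does
to future evidence. The intended users are foot-and-ankle surgeons,
pharmacy committees and health-economics analysts who want to rerun the
model with their own local prices and event rates.

## The model

With `S` annual surgeries, per-course drug cost `C_d` (course price plus any
monitoring add-on, e.g. INR testing for warfarin), per-event treatment cost
`C_t` and initial symptomatic VTE rate `VR_i`, drug spending balances averted
treatment spending at the break-even final rate

```
VR_f = (C_t · VR_i · S − C_d · S) / (C_t · S) = VR_i − C_d / C_t
```

The volume `S` cancels. The required absolute risk reduction and number
needed to treat are

```
ARR = VR_i − VR_f = C_d / C_t        NNT = 1 / ARR
```

A regimen is *cost-effective* when the required ARR does not exceed the
initial rate, i.e. `VR_f ≥ 0`; a negative `VR_f` means the drug would have
to prevent more events than occur. The package adds the two threshold
solvers implied by the equation (`C_t* = C_d / VR_i`, the treatment cost at
which a drug starts to break even, and `C_d* = C_t · VR_i`, its break-even
purchase price), one-way sensitivity sweeps over initial rates and
treatment costs, a two-proportion sample-size calculator showing why the
equivalent trial is infeasible, and a seeded synthetic-cohort generator
emulating the registry extract (prophylaxis flag + Bernoulli 4-week VTE
outcome) so the incidence pipeline is testable without database access.

## Worked example

The packaged drug-cost table holds the 1-month retail course prices
(aspirin 81 mg $0.30, aspirin 325 mg $1.62, enoxaparin 40 mg $138.77,
rivaroxaban 20 mg $504.23, warfarin 5 mg $2.10; INR monitoring adds $6.19
to warfarin). Running the full grid at the $9407 treatment cost:

```
$ vtecost breakeven --treatment-cost 9407 --rates 0.0046,0.0101,0.098
| drug             | axis | final_rate_pct | arr_pct | nnt   | cost_effective |
| ---------------- | ---- | -------------- | ------- | ----- | -------------- |
| Aspirin 81       | 0.46 | 0.457          | 0.003   | 31357 | true           |
| Aspirin 81       | 1.01 | 1.007          | 0.003   | 31357 | true           |
...
| Enoxaparin 40    | 0.46 | -1.015         | 1.475   | 68    | false          |
| Rivaroxaban 20   | 0.46 | -4.900         | 5.360   | 19    | false          |
| Rivaroxaban 20   | 9.80 | 4.440          | 5.360   | 19    | true           |
| Warfarin 5 + INR | 0.46 | 0.372          | 0.088   | 1135  | true           |
...
```

Read a row as: at a 0.46% baseline rate, aspirin 81 mg breaks even if it
lowers the rate to 0.457% — an ARR of 0.003% of patients, i.e. one
prevented event per 31,357 courses — so it is trivially cost-effective.
Enoxaparin at the same baseline would need a 1.48% ARR against a 0.46%
baseline (`final_rate` −1.015%): impossible, hence `false`. The expensive
agents only break even at the high 9.8% baseline, or at higher treatment
costs (`vtecost sweep --drug "Enoxaparin 40" --rate 0.0046 --costs
9407,30000,50000,70000,90000,110000` shows enoxaparin's verdict flipping
between $30,000 and $50,000; the exact threshold is
`threshold_treatment_cost` = $30,167.39).

The synthetic registry stand-in:

```
$ vtecost simulate --n 3455 --prophylaxis-fraction 0.543 --rate 0.0101 --seed 7
{
  "n_total": 3455,
  "n_no_prophylaxis": 1588,
  "n_events": 15,
  "rate_pct": 0.94,
  "ci95_pct": [0.57, 1.55],
  "seed": 7
}
```

One seeded draw of a registry-sized cohort: 1588 patients without
prophylaxis, 15 events, an estimated incidence of 0.94% with a 95% Wilson
interval covering the 1.01% truth the generator was given.

The same pipeline is scriptable from Python (`packaged_drug_table`,
`break_even_rate`, `sweep_initial_rates`, `generate_cohort`, …) and from a
flat YAML config via `run_breakeven`, which writes CSV/markdown tables plus
a JSON manifest recording every resolved input for reproducibility.

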