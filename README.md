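# rrmmcea

Cost-utility and budget-impact modelling of second-line treatment for
relapsed/refractory multiple myeloma (RRMM) in the South African public
health sector.

Multiple myeloma is incurable; after first-line therapy every patient
eventually relapses. The public-sector standard of care at relapse is oral
dexamethasone (DEX); the novel alternatives are bortezomib monotherapy (BORT)
and lenalidomide plus dexamethasone (LEN/DEX), which extend survival but at
drug prices that are very high relative to the health system's
willingness-to-pay. This package implements the decision-analytic pipeline a
health-technology-assessment unit would use to weigh those trade-offs, for
analysts who want the whole chain — model inputs to threshold prices — as
tested, scriptable code rather than a spreadsheet or proprietary tree model.

## The model

A closed cohort moves through three health states — pre-progression (stable
disease on treatment), progression, and dead — in 195 cycles of 28 days
(≈ 15 years). Transition probabilities are time-inhomogeneous, with segment
switches after cycles 6 and 26, and death absorbing:

    x_c = x_{c-1} P(c),        x_0 = (1, 0, 0)

Outcomes are quality-adjusted life years (QALYs) with utilities
u = (0.81 → 0.77 after two years, 0.64, 0), and costs (2021 ZAR) combine
tiered drug schedules, outpatient infusion/non-infusion tariffs and inpatient
days, both discounted at r = 5 %/year:

    QALY = Σ_c x_{c-1}·u(c) · (28/365.25) · (1+r)^(−28c/365.25)

Strategies are ordered by cost; incremental cost-effectiveness ratios
ICER = ΔC/ΔE are read off the efficiency frontier after removing strictly and
extended-dominated strategies, and compared with South African
cost-effectiveness thresholds (R38 500 per DALY averted; R32 659–R131 006 per
QALY). On top of the base case the package provides one-way deterministic
sensitivity analysis with tornado ordering, a price-threshold bisection (the
drug-price cut at which a regimen becomes cost-effective), a scenario
analysis on reduced strategy sets, a 1-year budget impact analysis for the
target population of 337 patients, a seeded synthetic-parameter generator,
and an individual-level microsimulation oracle used to validate the cohort
engine.

## Worked example

```python
from rrmmcea import base_case, evaluate_all, compute_icers, threshold_price

params = base_case()                      # bundled 2021 ZAR inputs
table = compute_icers(evaluate_all(params))
for e in table.entries:
    print(f"{e.regimen:8s} R{e.total_cost:>12,.0f} {e.total_qalys:.2f} {e.icer_label}")

bort = threshold_price(params, "BORT", params.cets.high_cet)
print(f"BORT price cut for cost-effectiveness: {bort.reduction_pct:.1f}%")
```

prints

```
DEX      R       8,332 1.01
BORT     R     294,037 1.54 532617
LEN/DEX  R   1,109,202 2.13 1398270
BORT price cut for cost-effectiveness: 85.8%
```

Reading: DEX costs R8 332 per patient from relapse to death and yields 1.01
discounted QALYs. BORT adds 0.54 QALYs at R532 617 per QALY gained and
LEN/DEX a further 0.58 at R1 398 270 per QALY — both more than four times the
highest South African threshold (R131 006/QALY), so neither is
cost-effective at current prices; the bortezomib price would have to fall by
about 86 % to change that verdict. The same analyses are scriptable from the
shell (`rrmmcea cea`, `rrmmcea dsa`, `rrmmcea threshold --regimen BORT --cet
131006`, `rrmmcea bia`, …), each run writing CSV/JSON reports plus a
manifest with the config checksum.

Note that these figures differ somewhat from the originally published ones
(e.g. 1.14/1.49/2.22 QALYs): the printed transition probabilities are rounded
to two decimals, and the survival of a 195-cycle geometric process is
sensitive to that last digit. `docs/methods.md` discusses the gap and why it
cannot be closed from the printed inputs alone.

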