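# Methods

## Model structure and assumptions

The decision problem is the choice of second-line therapy for
relapsed/refractory multiple myeloma (RRMM) in the South African public
sector: dexamethasone monotherapy (DEX, standard of care), bortezomib
monotherapy (BORT), or lenalidomide plus dexamethasone (LEN/DEX). A closed
cohort enters in the pre-progression state (stable disease on second-line
treatment) and transitions each 28-day cycle among three states —
pre-progression, progression, dead — for 195 cycles, a horizon of just under
15 years chosen as the plausible maximum survival for a cohort entering at a
median age of 63. Death is absorbing and there is no return from progression
to pre-progression. Background (other-cause) mortality is deliberately
excluded; the bounded horizon stands in for it.

Transition probabilities are time-inhomogeneous. Each regimen has three
segments — cycles 1–6, 7–26, 27 onward — reflecting hazard changes after six
and twenty-six months on treatment; one model cycle is identified with one
"month" of the source probability tables (the only self-consistent reading of
monthly probabilities in a 28-day-cycle model). The comparator matrices can
also be derived from a reference schedule by multiplying exit probabilities
by progression/mortality hazard ratios (`derive_schedule_from_hazard_ratios`),
but the bundled base case uses the published matrices directly.

### Row renormalization

The published matrices are printed to two decimals and several rows sum to
0.99 or 1.01. A valid stochastic process requires unit row sums, so every row
is divided by its sum on ingestion (`normalize_matrix`); the perturbation is
below the reporting precision of the source. Row sums outside [0.9, 1.1] are
treated as data errors, not drift.

### Reward conventions

Per-cycle rewards (utilities and costs) accrue at the start of each cycle on
the entering occupancy `x_{c-1}`, discounted with the factor
`(1+r)^(−28c/365.25)` of the cycle being lived. No half-cycle correction is
applied by default — the source analysis gives no indication of one — but a
`half_cycle_correction` flag switches rewards to the mid-cycle mean of the
boundary occupancies. The pre-progression utility falls from 0.81 to 0.77
"after two years", implemented as cycle 27 onward so that the utility switch
coincides with the 26-cycle transition-probability switch; the alternative
reading (cycle 25, i.e. 24 × 28-day cycles) changes total QALYs by < 0.001
and is not used.

## Parameters

All monetary values are 2021 ZAR. The inflation rate (5.1 %/yr) and USD/ZAR
rate (14.67) are carried as currency metadata only.

| Parameter | Default | Unit |
|---|---|---|
| Cycle length / horizon | 28 / 195 | days / cycles |
| Discount rate (costs and outcomes) | 0.05 | per year |
| Utilities: pre-progression early/late, progression | 0.81 / 0.77 / 0.64 | weight |
| Inpatient day / outpatient NIC / outpatient IC | 4 515.80 / 800 / 2 837 | ZAR |
| DEX 40 mg / LEN 25 mg / BORT per mg | 6.28 / 1 340.03 / 865.47 | ZAR |
| Dosing: DEX | 480 mg cycles 1–4, 160 mg after | per cycle |
| Dosing: BORT | 13.5 mg cycles 1–8, 9 mg after | per cycle |
| Dosing: LEN | 21 × 25 mg every cycle | per cycle |
| Utilisation (inpatient days; outpatient visits) | DEX 0.02; 0.3875 · BORT 0.0158; 0.5025 · LEN/DEX 0.0125; 0.3325 | per cycle |
| Cost-effectiveness thresholds | 38 500 (32 659–131 006) | ZAR/QALY |
| BIA population / budget year | 337 / 13 cycles | patients / cycles |

Design choices where the source is silent or ambiguous:

- **Cost accrual states.** Drug and utilisation costs accrue in both alive
  states by default (configurable). This is the only uniform convention that
  reconciles the published DEX lifetime cost (R8 312 vs R8 332 here) and the
  BORT first-year budget totals; conventions that stop drug costs at
  progression undershoot those anchors badly.
- **Bortezomib is priced per mg** (cycle cost = mg × price/mg) with no vial
  rounding or wastage, matching the granularity of the published unit costs.
- **The LEN/DEX arm includes the oral dexamethasone component**, priced with
  the same 480/160 mg tiering as DEX monotherapy; it contributes < 0.1 % of
  the arm's drug cost.
- **Single-exit-price conversion** for private-sector drugs is a scalar 40 %
  reduction helper (`adjust_private_price`); no live price lookups.
- **A budget year is 13 cycles (364 days)** — the whole-cycle count nearest a
  calendar year — and first-year budget costs are undiscounted, standard
  budget-impact practice (a flag enables within-year discounting; it changes
  totals by < 3 %).

## Frontier and dominance

Strategies are sorted by ascending cost (ties: QALYs descending, then input
order, with exact duplicates flagged). Strict dominance (no cheaper-or-equal,
at-least-as-effective alternative) is marked first; extended dominance is
then removed iteratively — any interior frontier strategy whose incremental
ratio exceeds that of the next more effective strategy is dropped and the
ICER chain recomputed — leaving strictly increasing frontier ICERs. Both
labels print as "Dominated" in reports. ICERs are always computed from
unrounded accumulations; rounding happens only at presentation. A frontier
strategy is cost-effective at a threshold iff its ICER ≤ threshold.

## One-way sensitivity analysis

The default grid varies: discount rates over {0, 10 %} (both costs and
outcomes jointly); outpatient tariffs (NIC and IC jointly) and the inpatient
day cost by ±50 %; lenalidomide and bortezomib prices by ±40 %; the
pre-progression utilities from −50 % up to the perfect-health ceiling of 1;
and every transition exit probability (3 regimens × 3 segments × 3 exits) by
±50 %. Scaled probabilities are clamped to [0, 1] first and then to the mass
left by the row's other exits, with the on-diagonal stay probability
absorbing the change — the minimal row-preserving rule consistent with
"capped at 1". Tornado output orders analyses by the width of the pivot
strategy's frontier-ICER range; an end where the pivot is dominated counts as
infinite width, and width ties fall back to name order.

## Threshold prices

`threshold_price` bisects a multiplier m ∈ [0, 1] on the regimen's drug unit
price until the frontier ICER equals the willingness-to-pay threshold
(relative tolerance 1e-4, at most 60 iterations), recomputing the full
frontier at each iterate so the comparator can change as dominance shifts.
Validity rests on the frontier ICER being monotone non-decreasing in the
regimen's own price, which the test suite verifies by grid sweep; the
bisection is also cross-checked against a 1 000-point grid-search oracle.
A regimen already cost-effective returns a 0 % reduction; one whose ICER
exceeds the threshold even at a free drug is reported as not achievable by
price alone.

## Budget impact

Per-patient first-year costs follow the Markov trace (survival-adjusted, not
full persistence), multiplied by population × coverage × uptake fraction and
therefore exactly linear in all three. Percentage increases are reported
against the DEX scenario under identical settings; the sensitivity grid
additionally reports percentage change against the scenario's own base mix,
since published grids are ambiguous about the reference.

## Synthetic data and the microsimulation oracle

`generate_parameter_set` perturbs a template (the bundled base case) with
seeded uniform multipliers on prices, utilisation rates, utilities and exit
probabilities, optionally randomizing segment boundaries. Every draw is run
through the full validator: row-stochastic matrices with absorbing death and
no recovery, utilities ordered pre-progression ≥ progression ≥ 0,
non-negative costs. Degenerate (1, 1) ranges reproduce the template exactly.
What it emulates is the *structure* of real parameter sets, not their
epidemiology: draws are independent across parameters, so correlations a real
evidence base would induce (e.g. between progression and mortality hazards)
are absent, and passing tests demonstrate structural correctness of the
pipeline, not clinical validity of any particular draw.

`microsimulate` replays a schedule at the individual level with per-cycle
categorical draws, accruing QALYs and costs under exactly the cohort engine's
start-of-cycle conventions, so discrepancies isolate engine bugs rather than
convention drift. The tests require cohort-vs-microsimulation occupancy
agreement within 3.5 binomial standard errors per state per cycle at
n = 100 000 on the base case, mean QALY/cost agreement within 3.5 Monte Carlo
standard errors at n = 200 000, and the 1/√n error decay across n = 10³–10⁵.
These sizes keep the full suite under half a minute on one CPU.

## Known limitations

- **The published headline figures are not exactly recoverable from the
  published inputs.** The original analysis ran on unrounded transition
  probabilities (derived from external reference probabilities and hazard
  ratios that were never printed); the printed two-decimal matrices are all
  that survives. Long-horizon occupancy is geometric-like in the stay
  probabilities, so half-a-last-digit rounding moves lifetime QALYs by
  several percent: this package computes 1.01 / 1.54 / 2.13 QALYs against the
  published 1.14 / 1.49 / 2.22, and a bounded search over rounding-consistent
  matrices shows the DEX figure is unreachable from the printed rows under
  any accrual convention (its undiscounted ceiling is ≈ 1.10). Downstream
  quantities inherit the gap: ICERs land 5–19 % from the published values and
  the bortezomib threshold reduction computes to ≈ 86 % against the published
  93 %. The acceptance tests assert the published values at face value and
  fail honestly rather than loosening tolerances.
- The published drug-price sensitivity rows labelled ±40 % are arithmetically
  consistent with the wider literature-based price bounds used in the budget
  grid (×⅓ to ×1⅔ for lenalidomide), not with ±40 %; this package implements
  the stated ±40 %.
- No probabilistic sensitivity analysis, adverse-event disutilities,
  comorbidity costs, background mortality, multi-year budget projection or
  vial-wastage modelling; these are out of scope by design.
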