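# Methods

## Model structure

The model couples a decision tree (strategy assignment at entry) to a
five-state Markov cohort chain with annual cycles: dialysis, KT (the
transplant year), 1-year post-KT, subsequent-years post-KT, and death.
A closed cohort enters at age 50 — in the KT state for preemptive
living-related transplantation (P-LRKT), on dialysis for the two
non-preemptive strategies — and is propagated to a lifetime horizon (age
100, or earlier once living occupancy falls below 1e-9; residual mass at
the horizon triggers a warning and truncation).

The thirteen per-cycle transition probabilities are assembled row-wise.
Death is applied first; the conditional non-death moves are scaled by
(1 − p_death) so every row sums to one exactly:

* dialysis → KT: the strategy's annual access probability (0.36 LRKT,
  0.18 DDKT, 0 for P-LRKT after entry), available only while the cohort age
  is at most 65 (the oldest age at which a transplant is performed);
* KT → dialysis: first-year graft loss 0.04; the two post-KT states return
  to dialysis at 0.01/year;
* each living state → death per the mortality model below;
* death is absorbing.

Internally the engine carries the dialysis state as two compartments
(never-transplanted vs post-graft-failure) so the `allow_retransplant`
switch (default on: failed grafts regain the strategy's access probability
while age ≤ 65) does not break the Markov property; traces report the
merged state.

## Mortality

General-population annual death probabilities q(age) are converted to
hazard rates, multiplied by the age-banded standardized mortality ratio of
dialysis-dependent ESKD (8.6 at 50–59, 4.6 at 60–69, 1.9 at 70–79, 7.8 at
≥80 — used as printed in the source inputs, including the non-monotone ≥80
value), and converted back to probabilities. The three transplanted states
use the same bands divided by the pooled ESKD-vs-KT mortality ratio 2.19.
Scaling on the rate scale rather than the probability scale is the
actuarially standard choice and keeps results in [0, 1] for any multiplier.

The packaged default life table is synthetic: a Gompertz–Makeham hazard
h(x) = c + a·e^(bx) with a = 2.40834e-5, b = 0.098983, c = 4e-4, solved so
that period life expectancy matches WHO Thailand 2019 landmarks (77.5 years
at birth, 21.3 at age 60; the resulting q(50) = 0.0038, q(70) = 0.025,
q(80) = 0.064). It stands in for the WHO life table, which is an external
download; any real table can be supplied as a two-column CSV (age, q).

## Costs, utilities, accrual

All costs are 2020 USD from a societal perspective without productivity
losses. Each cycle accrues occupancy-weighted state costs, the per-visit
transplant cost for new entrants to the KT state, life-years over living
occupancy and utility-weighted QALYs (dialysis 0.68, KT 0.781, both post-KT
states 0.889), all on cycle-start membership with no half-cycle correction,
discounted at (1+r)^(−t) with r = 0.03 and t = 0 at entry. The P-LRKT
pre-transplant work-up ("waiting") cost of 6,879 USD is charged once at
entry.

Cost attachment (`cost_attachment` setting): by default each state carries
the cost bearing its name — the KT state only the per-visit transplant cost
(7,816 / 9,104 / 13,908 USD by strategy), the 1-year-post state the
first-year cost (17,592 / 15,453 / 19,520 USD/yr), the subsequent state the
subsequent-year cost (9,886 / 11,709 / 10,478 USD/yr). This literal mapping
reproduces the published per-strategy lifetime costs to within 1.2%,
whereas the alternative `first_year_at_kt` mapping (first-year annual cost
loaded onto the transplant year, both post-KT states at the subsequent-year
cost) overshoots them by 4–6.5%; the alternative remains available as a
configuration switch. The dialysis state costs 13,734 USD/yr plus the
shared direct non-medical cost of 1,059 USD/yr; a literature-based
profile (12,193 USD/yr plus 12 × 481 USD/mo complication costs) is
selectable via `dialysis_costing: literature`. Dialysis and non-medical
costs are single parameters shared by all strategies (one tornado bar, one
PSA draw), since they represent one measured quantity.

## Uncertainty analysis

**One-way (tornado).** Each parameter moves to its bounds with everything
else at base case: explicit bounds where stated (discount rate 0–0.06),
else value ± 1.96·SE, else ±15%; probabilities and utilities are clamped to
[0, 1] and costs to ≥0. The recorded outcome is the incremental cost of
P-LRKT vs NP-DDKT by default (that comparison is cost-saving, so an ICER is
undefined); incremental net monetary benefit is available via
`metric="nmb"` and is the metric under which utility parameters can
register at all.

**Probabilistic.** 1,000 Monte Carlo draws; probabilities and utilities are
drawn from method-of-moments beta distributions, costs from
method-of-moments gamma distributions (fits round-trip the printed mean and
SE to 1e-12; an SE that violates the beta feasibility condition
se² < m(1−m) is shrunk to 0.99·√(m(1−m)) with a warning). All parameters
are drawn independently; one joint draw is shared across the three
strategies (common random numbers) so incremental results reflect parameter
uncertainty only. The SMR bands and the 2.19 ratio are held fixed between
draws by default — the source inputs print SEs for them but no distribution
family — and can be included via `vary_mortality_in_psa: true` (gamma).
Results are summarised as cost-effectiveness-plane quadrant fractions
(below-line: ΔCost < WTP·ΔQALY), and as acceptability curves over a WTP
grid of 0–20,000 USD/QALY in steps of 250, with NMB ties splitting
probability mass equally.

## Synthetic cohort generator

`generate_cohort` emulates the transplant-centre database that the model's
cohort-derived inputs came from: 40 P-LRKT / 50 NP-LRKT / 50 NP-DDKT
patients by default, followed up to 10 years, all entering at the model
start age. Waiting times are geometric (the memoryless annual access
probability, matching the Markov assumption rather than any empirical
waiting-time distribution), graft failure uses the first-year/subsequent
probabilities, death follows the mortality model, and every observed
state-year draws a cost from the moment-matched gamma of that state's mean
(per-year SD equal to the printed SE). `estimate_inputs` recovers
transition probabilities as events over person-years at risk (conditional
on surviving the year, matching the engine's death-first ordering) with
binomial SEs, and mean costs with SE = SD/√n; zero-exposure quantities are
reported missing, not zero. What passing recovery tests show is therefore
internal consistency of the estimation-to-model pipeline — the generator
makes no attempt to emulate demographics, utility measurement, or
cost-to-charge conversion of real hospital data.

## Numerical choices

* Occupancy conservation is asserted each cycle (1e-9).
* `dsa_bounds` always brackets the base value after clamping.
* Exact outcome ties classify as cost-effective; strict dominance means
  at least equal QALYs for strictly less money.
* ICERs are reported unrounded internally; tables round to 2 decimals.
* Seeds: every stochastic routine takes an explicit seed; identical seeds
  give bit-identical outputs on one platform.

## Calibration and known limitations

The packaged configuration reproduces the published per-strategy lifetime
costs closely (P-LRKT +0.2%, NP-DDKT −0.5%, NP-LRKT −1.2%) and the
published dominance structure (P-LRKT cost-saving against both
comparators; NP-LRKT dominated and, vs NP-DDKT, above the WTP threshold).
It does **not** reproduce the published life-expectancy and QALY columns:
this implementation yields 15.3/13.2 (P-LRKT), 14.3/11.6 (NP-DDKT) and
14.9/12.6 (NP-LRKT) discounted LY/QALY against published values of
16.00/14.12, 15.70/13.65 and 16.00/14.12. The published outcome columns
are not attainable from the published inputs by any coherent chain of this
structure: a QALY gap of 0.47 at a life-year gap of 0.30 with utilities
0.68 (dialysis) and 0.889 (post-KT) implies only ~1.2 excess discounted
dialysis-years for NP-DDKT, whereas an annual access probability of 0.18
implies ~4; likewise NP-LRKT cannot match P-LRKT's outcomes exactly while
spending ~2.4 expected years on dialysis at 8.6-fold mortality, and a
discounted life expectancy of 16.0 from age 50 nearly equals the
general-population ceiling (~18.4 under the default table) despite 2–4×
mortality multipliers. The same structural excess of dialysis time widens
the variance of the incremental cost in the probabilistic analysis, so
plane fractions that depend on it (below-line fraction for P-LRKT vs
NP-DDKT; above-line fraction for NP-LRKT vs NP-DDKT) sit several points
from the published 86.2% / 65.7%, while the cost-saving (dominant-quadrant)
fraction lands near the published 79.4%. These deviations are calibration
properties of the published totals, not tunables of this implementation,
and are asserted honestly in the acceptance tests.

Further limitations: single-sex, all-cause mortality; no tunnel states or
graft-count memory beyond the retransplant flag; no extended (only strict)
dominance; no EVPI; deceased-donor organ-procurement costs are excluded
from the inputs by design.
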