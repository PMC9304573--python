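# ktcea

Cost-utility analysis of kidney-transplantation strategies for adults with
end-stage kidney disease (ESKD), built as a decision tree feeding a
five-state Markov cohort model. The package compares three strategies in a
Thai treatment setting:

* **P-LRKT** — preemptive living-related kidney transplantation (transplanted
  before maintenance dialysis starts; the cohort enters the model in the KT
  state),
* **NP-LRKT** — non-preemptive living-related KT (enters on dialysis, annual
  transplant-access probability 0.36),
* **NP-DDKT** — non-preemptive deceased-donor KT (enters on dialysis, annual
  access probability 0.18).

It is aimed at health-economics analysts who want a scriptable, testable
version of this class of model: base-case lifetime costs/QALYs, ICER and
dominance analysis, one-way (tornado) and probabilistic sensitivity analysis
with cost-effectiveness plane and acceptability curves, plus a synthetic
patient-level cohort generator for end-to-end testing of the
estimation-to-model pipeline.

## Model

Health states: dialysis → KT → 1-year post-KT → subsequent-years post-KT →
death, with annual cycles and a lifetime horizon. Within a cycle death is
applied first (probability from a general-population life table scaled on the
hazard scale by an age-banded standardized mortality ratio, divided by a
pooled ESKD-vs-KT mortality ratio of 2.19 for transplanted states); surviving
mass then moves by the transplant-access and graft-loss probabilities
(4%/year in the first post-transplant year, 1%/year thereafter). Costs
(2020 USD), life-years and utilities (dialysis 0.68, KT 0.781, post-KT 0.889)
accrue on cycle-start membership and are discounted at 3%/year:

    total = Σ_t (1 + r)^(-t) · Σ_state occ(t, state) · payoff(state)

Strategies are compared by incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY against a willingness-to-pay threshold of 5,113 USD/QALY,
with a strategy called *cost-saving* when it yields at least equal QALYs for
strictly less money. The probabilistic analysis draws probabilities and
utilities from moment-matched beta distributions and costs from
moment-matched gamma distributions (1,000 Monte Carlo draws, common draws
across strategies).

All base-case inputs ship in
`src/ktcea/data/params_siriraj_2020usd.yaml`; the default life table is a
synthetic Gompertz–Makeham fit to WHO Thailand 2019 landmarks (see
`docs/methods.md`), and a real table can be supplied as a CSV of
(age, annual death probability).

## Worked example

```
$ ktcea run
== outcomes ==
strategy  total_cost  life_expectancy  qaly  cost_per_ly
  P-LRKT  170,684.14            15.32 13.20    11,142.75
 NP-LRKT  185,029.49            14.95 12.56    12,379.00
 NP-DDKT  179,397.73            14.31 11.63    12,538.22

== scenarios ==
reference comparator  incremental_cost  qaly_gained       icer     classification
   P-LRKT    NP-DDKT         -8,713.59         1.57  -5,566.86        cost-saving
   P-LRKT    NP-LRKT        -14,345.35         0.63 -22,604.84        cost-saving
  NP-LRKT    NP-DDKT          5,631.76         0.93   6,051.46 not cost-effective
```

Reading the output: preemptive LRKT accumulates the lowest discounted
lifetime cost (≈170,700 USD) *and* the most QALYs (13.20), so it dominates
both alternatives — it is cost-saving, and no ICER needs to be paid for its
extra benefit. Non-preemptive LRKT is the most expensive strategy and is
dominated by the preemptive option; compared with deceased-donor KT it buys
0.93 extra QALYs at ≈6,051 USD each, above the 5,113 USD/QALY threshold, so
it is not cost-effective at Thai willingness to pay.

Other entry points: `ktcea dsa` (tornado), `ktcea psa` (cost-effectiveness
plane), `ktcea ceac`, `ktcea simulate-cohort` (synthetic patient records and
parameter recovery), `ktcea report` (everything, with `--out DIR` writing
CSV tables, a seed- and config-hash-stamped `summary.json`, and optional
figures via `--figures`).

As a library:

```python
import ktcea

params = ktcea.load_parameters()            # packaged base case
outcomes = ktcea.evaluate_strategies(params)
psa = ktcea.run_psa(params, n=1000, seed=7)
curve = ktcea.ceac(psa)                     # acceptability curves
```

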