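# Default model inputs: Siriraj Hospital kidney-transplantation cohort, 2020 USD.
# Each parameter block: name, value (base case), se (standard error, optional),
# low/high (explicit deterministic-sensitivity bounds, optional),
# family (beta | gamma | fixed), role (probability | cost | utility | ratio | rate-config).
settings:
  discount_rate: 0.03
  discount_rate_low: 0.0
  discount_rate_high: 0.06
  wtp: 5113.0            # USD per QALY, Thai willingness-to-pay threshold
  start_age: 50
  kt_stop_age: 65        # oldest age at which a transplant is performed
  max_age: 100
  allow_retransplant: true
  cost_attachment: literal        # or: first_year_at_kt
  dialysis_costing: cohort        # or: literature
  vary_mortality_in_psa: false

parameters:
  # --- transition probabilities (annual) ---
  - {name: p_dialysis_to_kt_lrkt, value: 0.36, se: 0.084, family: beta, role: probability, units: per year}
  - {name: p_dialysis_to_kt_ddkt, value: 0.18, se: 0.041, family: beta, role: probability, units: per year}
  - {name: p_graft_loss_year1, value: 0.04, se: 0.004, family: beta, role: probability, units: per year}
  - {name: p_graft_loss_subsequent, value: 0.01, se: 0.001, family: beta, role: probability, units: per year}

  # --- mortality multipliers (dialysis vs general population, by age band) ---
  - {name: smr_50_59, value: 8.6, se: 0.3061, family: fixed, role: ratio, units: ratio}
  - {name: smr_60_69, value: 4.6, se: 0.2041, family: fixed, role: ratio, units: ratio}
  - {name: smr_70_79, value: 1.9, se: 0.1531, family: fixed, role: ratio, units: ratio}
  - {name: smr_80_plus, value: 7.8, se: 0.1531, family: fixed, role: ratio, units: ratio}
  - {name: eskd_vs_kt_mortality_ratio, value: 2.19, se: 0.352, family: fixed, role: ratio, units: ratio}

  # --- costs shared across strategies ---
  - {name: cost_dialysis, value: 13734.0, se: 2060.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_direct_nonmedical, value: 1059.0, se: 257.0, family: gamma, role: cost, units: USD/yr}
  # literature-based alternative dialysis costing (used when dialysis_costing: literature)
  - {name: cost_dialysis_literature, value: 12193.0, se: 4236.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_dialysis_complication_monthly, value: 481.0, se: 481.0, family: gamma, role: cost, units: USD/mo}

  # --- preemptive living-related KT ---
  - {name: cost_kt_plrkt, value: 7816.0, se: 507.0, family: gamma, role: cost, units: USD/visit}
  - {name: cost_post1_plrkt, value: 17592.0, se: 1139.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_subsequent_plrkt, value: 9886.0, se: 584.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_waiting_plrkt, value: 6879.0, se: 917.0, family: gamma, role: cost, units: USD}

  # --- non-preemptive living-related KT ---
  - {name: cost_kt_nplrkt, value: 9104.0, se: 1070.0, family: gamma, role: cost, units: USD/visit}
  - {name: cost_post1_nplrkt, value: 15453.0, se: 1067.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_subsequent_nplrkt, value: 11709.0, se: 825.0, family: gamma, role: cost, units: USD/yr}

  # --- non-preemptive deceased-donor KT ---
  - {name: cost_kt_npddkt, value: 13908.0, se: 1545.0, family: gamma, role: cost, units: USD/visit}
  - {name: cost_post1_npddkt, value: 19520.0, se: 1361.0, family: gamma, role: cost, units: USD/yr}
  - {name: cost_subsequent_npddkt, value: 10478.0, se: 440.0, family: gamma, role: cost, units: USD/yr}

  # --- health-state utilities ---
  - {name: utility_dialysis, value: 0.68, se: 0.1, family: beta, role: utility, units: utility}
  - {name: utility_kt, value: 0.781, se: 0.117, family: beta, role: utility, units: utility}
  - {name: utility_post1, value: 0.889, se: 0.133, family: beta, role: utility, units: utility}
  - {name: utility_subsequent, value: 0.889, se: 0.133, family: beta, role: utility, units: utility}
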