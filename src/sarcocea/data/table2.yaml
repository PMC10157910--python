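# Reference model configuration: global parameters and the eight management
# strategies (seven interventions plus no-intervention) with their reported
# means, uncertainty, and distribution families.
#
# Monetary values are 2022 PPP dollars.  `frr_*` are percent fall-risk
# reductions via muscle mass (mm), muscle strength (ms) and muscle
# performance (mp); beta distributions for them are rescaled to [0, 100].
# The vitamin-D-alone annual cost is not reported directly; it is recovered
# as the (P+D) - P cost difference (129.276), which matches the
# (D+E) - E difference to three decimals; its sd uses the 20%-of-mean
# convention applied when no uncertainty is reported.
name: sarcopenia-iran-2022
parameters:
  discount_rate_costs: {value: 0.05, dist: beta, range: [0.02, 0.10]}
  discount_rate_outcomes: {value: 0.05, dist: beta, range: [0.03, 0.08]}
  q60_background: 0.0095
  hr_sarcopenia_mortality: {value: 1.6, dist: lognormal, ci95: [1.24, 2.06]}
  rr_fracture_mortality_y1: {value: 6.57, dist: lognormal, ci95: [5.54, 7.29]}
  p_fall: {value: 0.155, dist: beta, sd: 0.041}
  p_fracture_given_fall: {value: 0.33, dist: beta, sd: 0.06}
  utility_sarcopenic: {value: 0.785, dist: beta, sd: 0.1962}
  disutility_fracture_y1: {value: 0.25, dist: beta, sd: 0.025}
  disutility_post_fracture: {value: 0.17, dist: beta, sd: 0.017}
  cost_fracture_y1: {value: 12588.214, dist: gamma, sd: 3147.053}
  cost_post_fracture: {value: 2517.64, dist: gamma, sd: 503}
  cost_visits_labs: 400.409
  wtp: 25249.13
  ppp_rial_per_dollar: 29704
strategies:
  - name: "None"
    acceptance: 0.0
    annual_cost: 0.0
    dosage_note: "No intervention (natural history)"
  - name: "E"
    acceptance: 0.9
    dosage_note: "3 training sessions of 1.5 h per week"
    annual_cost: {value: 4268.785, dist: gamma, sd: 853.75}
    frr_mm: {value: 14.0, dist: beta, sd: 3.5}
  - name: "P"
    acceptance: 0.9
    dosage_note: "Whey protein 45 g/day"
    annual_cost: {value: 5463.329, dist: gamma, sd: 1515.555}
    frr_mm: {value: 3.64, dist: beta, sd: 0.91}
    frr_ms: {value: 1.6, dist: beta, sd: 0.4}
    frr_mp: {value: 8.82, dist: beta, sd: 2.205}
  - name: "D"
    acceptance: 0.9
    dosage_note: "Vitamin D 800 IU/day"
    annual_cost: {value: 129.276, dist: gamma, sd: 25.8552}
    frr_mp: {value: 27.08, dist: beta, sd: 6.77}
  - name: "WBV"
    acceptance: 0.9
    dosage_note: "3 sessions per week"
    annual_cost: {value: 7126.312, dist: gamma, sd: 1790.565}
    frr_ms: {value: 1.15, dist: beta, sd: 0.2875}
    frr_mp: {value: 33.23, dist: beta, sd: 8.3075}
  - name: "P+D"
    acceptance: 0.9
    dosage_note: "Vitamin D 800 IU/day + Whey protein 45 g/day"
    annual_cost: {value: 5592.605, dist: gamma, sd: 1536.569}
    frr_mm: {value: 46.52, dist: beta, sd: 11.63}
    frr_ms: {value: 1.6, dist: beta, sd: 0.4}
    frr_mp: {value: 20.1, dist: beta, sd: 5.025}
  - name: "D+E"
    acceptance: 0.9
    dosage_note: "Vitamin D 800 IU/day + 3 training sessions of 1.5 h per week"
    annual_cost: {value: 4398.06, dist: gamma, sd: 1662.537}
    frr_mm: {value: 15.31, dist: beta, sd: 3.8275}
    frr_ms: {value: 3.7, dist: beta, sd: 0.925}
  - name: "P+D+E"
    acceptance: 0.9
    dosage_note: "Whey protein 45 g/day + Vitamin D 800 IU/day + 3 training sessions of 1.5 h per week"
    annual_cost: {value: 9861.39, dist: gamma, sd: 7477.532}
    frr_mm: {value: 24.35, dist: beta, sd: 6.0875}
    frr_ms: {value: 3.85, dist: beta, sd: 0.962}
    frr_mp: {value: 37.33, dist: beta, sd: 9.332}
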