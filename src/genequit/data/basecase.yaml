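# Base-case configuration: two-strategy smoking-cessation cost-effectiveness
# model (usual care = NRT + counselling, vs. usual care + lung-cancer
# genetic test), 2009 AU$, payer perspective.
cohort:
  start_age: 50
  horizon: 35
  sex: both
economics:
  discount_rate: 0.05
  wtp: 20000.0
strategies:
  usc:
    name: NRT + counselling (usual smoking cessation)
    quit_rate_12m: 0.06
    relapse_multiplier: 1.0
    cost_items:
      - {label: GP visit, quantity: 1, unit_cost: "21.00"}
      - {label: Patches 21mg (6 packs), quantity: 6, unit_cost: "47.95"}
      - {label: Patches 14mg (2 packs), quantity: 2, unit_cost: "27.95"}
      - {label: Patches 7mg (2 packs), quantity: 2, unit_cost: "27.95"}
      - {label: Phone counselling, quantity: 5, unit_cost: "75.74"}
      - {label: Self-help booklet, quantity: 1, unit_cost: "2.90"}
  gt:
    name: NRT + counselling + genetic test
    quit_rate_12m: 0.11
    relapse_multiplier: 1.0
    cost_items:
      - {label: GP visit, quantity: 1, unit_cost: "21.00"}
      - {label: Patches 21mg (6 packs), quantity: 6, unit_cost: "47.95"}
      - {label: Patches 14mg (2 packs), quantity: 2, unit_cost: "27.95"}
      - {label: Patches 7mg (2 packs), quantity: 2, unit_cost: "27.95"}
      - {label: Phone counselling, quantity: 5, unit_cost: "75.74"}
      - {label: Self-help booklet, quantity: 1, unit_cost: "2.90"}
      - {label: Clinic visits for test, quantity: 2, unit_cost: "21.00"}
      - {label: Genetic test, quantity: 1, unit_cost: "311.00"}
      - {label: Test result booklet, quantity: 1, unit_cost: "2.90"}
relapse:
  bands: {early: 0.10, late: 0.04, early_through_year: 6, max_year: 120}
utilities:
  no_lung_cancer: 1.0
  early_lc: 0.73
  advanced_lc: 0.66
cancer_costs:
  early_first_year: 44274.0
  advanced_first_year: 27057.0
  ongoing_stable: 7115.0
  progressive: 10945.0
  terminal_final_year: 9961.0
stage_split_early: 0.20
progression_prob_early: 0.15
tunnel_years: 5
half_cycle_correction: false
smoker_mortality_multiplier: 1.0
# Uncertain parameters for the probabilistic sensitivity analysis: every
# scalar with a published one-way range (beta for probabilities/utilities)
# plus all cancer costs at +/-30% (gamma).
psa_distributions:
  quit_rate_gt: {family: beta, mean: 0.11, low: 0.07, high: 0.22}
  quit_rate_usc: {family: beta, mean: 0.06, low: 0.03, high: 0.12}
  stage_split_early: {family: beta, mean: 0.20, low: 0.13, high: 0.23}
  utility_early_lc: {family: beta, mean: 0.73, low: 0.69, high: 0.83}
  utility_advanced_lc: {family: beta, mean: 0.66, low: 0.30, high: 0.76}
  cost_early_first_year: {family: gamma, mean: 44274.0, low: 30991.8, high: 57556.2}
  cost_advanced_first_year: {family: gamma, mean: 27057.0, low: 18939.9, high: 35174.1}
  cost_ongoing_stable: {family: gamma, mean: 7115.0, low: 4980.5, high: 9249.5}
  cost_progressive: {family: gamma, mean: 10945.0, low: 7661.5, high: 14228.5}
  cost_terminal: {family: gamma, mean: 9961.0, low: 6972.7, high: 12949.3}
epi:
  synthetic: {}
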