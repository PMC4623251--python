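# Peru 2012 scenario: one-year decision-tree model of diabetic-foot prevention
# among Type 2 diabetics at high risk of ulceration (severe neuropathy).
#
# All proportions are decimals. Monetary values are 2012 US$ unless noted.
# The baseline ulcer prevalence and the effectiveness of standard care plus
# temperature monitoring are stored as derivations so full precision is kept:
# the widely quoted 22.18 % and 78.81 % are display roundings.
epidemiology:
  total_diabetes_population: 942000
  high_risk_fraction: 0.219
  baseline_ulcer_prevalence:
    # trial ulceration rate under standard care, and the effectiveness of
    # standard care relative to sub-optimal care: baseline = 0.122 / (1 - 0.45)
    reference_prevalence: 0.122
    reference_effectiveness: 0.45
  p_hospital: 0.30
  p_outpatient: 0.70
  p_amputation_heal: 0.4775
  p_debridement_heal: 0.3945
  p_death: 0.128
  p_major_given_amputation: 0.558
  p_minor_given_amputation: 0.442

strategies:
  sub_optimal:
    effectiveness: 0.0
    # per-person/year; implied values (strategy totals / 206,298 high-risk
    # persons); display_cost is the rounded figure usually quoted
    prevention_cost_per_person: 64.71591096375147
    display_cost: 65
  standard:
    effectiveness: 0.45
    prevention_cost_per_person: 184.82954754772223
    display_cost: 185
  standard_plus_temp:
    # effectiveness derived from the trial ulceration rate of 4.7 % under
    # standard care plus temperature monitoring: 1 - 0.047 / baseline
    effectiveness:
      target_prevalence: 0.047
    prevention_cost_per_person: 406.45004798883167
    display_cost: 406

treatment_costs:   # US$ per episode
  wound_management: 79
  debridement: 1022
  minor_amputation: 5153
  major_amputation: 7360

economics:
  minimum_wage_local: 750      # PEN per month
  exchange_rate: 2.64          # PEN per US$
  discount_rate: 0.03          # per year
  retirement_age: 65           # years
  mean_age_at_death: 63        # years
  gdp_per_capita: 6568         # US$, 2012
  gdp_multiplier: 3            # cost-effectiveness threshold = 3 x GDP/capita

ranges:  # one-way sensitivity bounds, stored verbatim (mostly +/-30 %)
  baseline_ulcer_prevalence: [0.1553, 0.2884]
  effectiveness_standard: [0.30, 0.60]
  effectiveness_standard_plus_temp: [0.65, 0.85]
  p_hospital: [0.21, 0.39]
  p_outpatient: [0.61, 0.79]
  p_amputation_heal: [0.3343, 0.6208]
  p_debridement_heal: [0.2512, 0.5377]
  prevention_cost.sub_optimal: [45, 84]
  prevention_cost.standard: [129, 240]
  prevention_cost.standard_plus_temp: [285, 528]
  cost_major_amputation: [5152, 9568]
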