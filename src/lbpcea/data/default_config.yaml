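# Base-case configuration of the chronic low back pain cost-effectiveness model
# (usual care vs usual care + acupuncture collaborative treatment; 2009 KRW).
# Every model quantity lives here; the code carries no numeric literals for them.
model:
  n_cycles: 20                # quarterly cycles: five-year horizon
  cycle_length_years: 0.25
  annual_discount_rate: 0.05
  initial_state: acute
  cohort_size: 10000

conventions:
  reward_timing: start        # start-of-cycle occupancy earns each cycle's rewards
  half_cycle: false
  outcome_discounting: none   # headline totals undiscounted; per_cycle applies the 5% rate
  rr_scale: probability       # risk ratio multiplies the recovery probability, capped at 1
  cohort_timing: start        # population-EVPI cohorts arrive at the start of each year

mortality:
  kind: constant              # stand-in for a 60-year-old female; or kind: life_table
  per_cycle: 0.001

# point values and PSA distributions
# beta: a = alpha, b = beta; gamma: a = shape, b = scale; lognormal: a = log-mean, b = log-SE
parameters:
  tATC:      {value: 0.24,   dist: beta,      a: 29,     b: 91}        # acute -> chronic
  tWTC:      {value: 0.16,   dist: beta,      a: 26,     b: 137}       # well -> chronic (recurrence)
  tCTW:      {value: 0.35,   dist: beta,      a: 135,    b: 252}       # chronic -> well, usual care
  uALBP:     {value: 0.85,   dist: beta,      a: 3.97,   b: 0.70}      # acute-state utility
  uCLBPUC:   {value: 0.62,   dist: beta,      a: 13.99,  b: 8.57}      # chronic utility, usual care
  uCLBPACUC: {value: 0.65,   dist: beta,      a: 14.14,  b: 7.61}      # chronic utility, collaboration
  uWell:     {value: 0.96,   dist: beta,      a: 22.08,  b: 0.92}      # well-state utility
  cUC:       {value: 507776, dist: gamma,     a: 24.69,  b: 20566.20}  # KRW per cycle, usual care
  cACUC:     {value: 730329, dist: gamma,     a: 19.54,  b: 37372.18}  # KRW per cycle, collaboration
  tRR:       {value: 1.40,   dist: lognormal, a: 0.34,   b: 0.05}      # recovery risk ratio

costs:
  include_indirect: false     # base case excludes productivity loss
  indirect_nonmedical_per_cycle: 239142
  strategies:
    usual_care:
      direct_nonmedical: 232036
      visit_schedule:
        - {label: first visit, per_visit_cost: 53983, frequency: 1}
        - {label: regular visit (diagnosis and treatment), per_visit_cost: 31685, frequency: 6}
        - {label: simple visit (treatment only), per_visit_cost: 10549, frequency: 3}
    collaborative:
      direct_nonmedical: 296897
      visit_schedule:
        - {label: first visit, per_visit_cost: 57463, frequency: 1}
        - {label: regular visit (diagnosis and treatment), per_visit_cost: 50223, frequency: 6}
        - {label: simple visit (treatment only), per_visit_cost: 24877, frequency: 3}

psa:
  n_draws: 10000
  seed: 2010
  lambda_grid: {start: 0, stop: 20000000, step: 20000}   # KRW per QALY

voi:
  annual_incidence: 57400     # new chronic LBP cases per year
  horizon_years: 5
  discount_rate: 0.05
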