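# Default cohort configuration: training-cohort distribution moments
# (n = 351), published odds ratios for the progression model, and the
# constant annual transition rates.  The intercept is calibrated at run
# time so the cohort's expected PDR share matches target_pdr_prevalence.
n: 501
seed: 0

predictors:
  age: {family: normal, mean: 67.5, sd: 9.4, lower: 21, upper: 100}
  male: {family: bernoulli, p: 0.98291}
  dm_duration: {family: normal, mean: 21.5, sd: 9.0, lower: 0, upper: 80}
  bmi: {family: normal, mean: 32.2, sd: 6.3, lower: 12, upper: 70}
  hba1c: {family: normal, mean: 8.2, sd: 1.8, lower: 4, upper: 18}
  hypertension: {family: bernoulli, p: 0.98006}
  dyslipidemia: {family: bernoulli, p: 0.84615}
  nephropathy: {family: bernoulli, p: 0.35328}
  tobacco: {family: bernoulli, p: 0.25071}

rates:
  onset_annual: 0.077     # no retinopathy -> NPDR
  vl_annual: 0.007        # PDR -> vision loss
  entrant_no_dr: 0.715    # new entrants start without retinopathy
  prp_annual: 0.0         # photocoagulation back-transition, off by default

hazard:
  odds_ratios:
    dm_duration: 1.059
    nephropathy: 2.163
    bmi: 0.961
  intercept: calibrate

target_pdr_prevalence: 0.265
annual_hazard_scale: 1.0
include_no_dr: false
no_dr_prob: 0.0
record_history: false
life_table: null
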