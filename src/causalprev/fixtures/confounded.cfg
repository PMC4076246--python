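# Strongly confounded variant of the cohort simulator: education,
# marital status, and gravidity push both toward COC use and toward
# CIN2+, so the crude (and any unadjusted) contrast is visibly biased
# upward relative to the true marginal prevalence difference.  Used for
# the double-robustness and misspecification demonstrations.
n: 2519
seed: 0
beta_A:
  intercept: -2.4
  age_std: -0.40
  education: 0.80
  marital: 0.70
  gravidity: 0.15
  log_cd4_c: 0.30
beta_Y:
  intercept: -4.0
  age_std: 0.50
  education: 0.60
  marital: 0.50
  gravidity: 0.12
  log_cd4_c: -0.50
  A: 0.40
confounder_spec:
  age_min: 18
  age_max: 49
  education_probs: [0.15, 0.45, 0.30, 0.10]
  marital_p: 0.6
  gravidity_lambda: 3.0
  gravidity_max: 12
  cd4_log_mean: 5.5
  cd4_log_sd: 0.8
visit_spec:
  months_shape: 2.0
  months_mean: 24.0
  frac_alpha: 2.0
  frac_beta: 2.0
  fp_frac_alpha: 1.0
  fp_frac_beta: 6.0
miss_spec: {}
misclass:
  sensitivity: 1.0
  specificity: 1.0
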