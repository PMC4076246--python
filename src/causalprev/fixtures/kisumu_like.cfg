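# Default cohort-simulation fixture: a Kenyan HIV-care screening cohort
# of n = 2519 women under 50, ~35% COC ever-use, ~8.7% CIN2+ prevalence,
# true marginal prevalence difference psi ~ +0.029.
# Intercepts and the exposure coefficient were calibrated once by Monte
# Carlo (400k confounder draws) against those three targets and frozen.
n: 2519
seed: 0
beta_A:
  intercept: -1.098
  age_std: -0.30
  education: 0.25
  marital: 0.40
  gravidity: -0.05
  log_cd4_c: 0.15
beta_Y:
  intercept: -2.597
  age_std: 0.30
  education: -0.20
  marital: 0.10
  gravidity: 0.08
  log_cd4_c: -0.40
  A: 0.357
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
# MAR missingness driven only by always-observed columns (A, Y, age):
# ~17% of CD4 nadir cells (outcome-dependent), ~10% of education cells.
miss_spec:
  cd4_nadir:
    intercept: -1.6
    Y: 0.4
  education:
    intercept: -2.2
    A: 0.3
misclass:
  sensitivity: 1.0
  specificity: 1.0
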