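# Methods

## The estimation problem

The package targets the marginal prevalence difference
ψ = E[Y(1)] − E[Y(0)] for a binary exposure A (COC ever-use) and binary
outcome Y (CIN2+ at screening) in a cross-sectional cohort, under the
usual identification conditions: no unmeasured confounding given the
measured set W (age, education, marital status, gravidity, CD4+ nadir),
positivity, and consistency.  Identification questions themselves are
handled graphically in `causal_dag`; estimation assumes the reduced
W → A → Y structure.

## Cohort simulator

The simulator is a structural causal model with logistic links and
main-effects linear predictors:

- W: age ~ uniform integer on [18, 49]; education ~ categorical on four
  ordered levels with weights (0.15, 0.45, 0.30, 0.10), coded 0–3 in
  linear predictors; marital ~ Bernoulli(0.6); gravidity ~ Poisson(3)
  truncated at 12; CD4 nadir ~ log-normal(meanlog 5.5, sdlog 0.8)
  cells/µL.
- A | W ~ Bernoulli(expit(β_A·x(W))), Y | A, W ~ Bernoulli(expit(β_Y·x(W, A))).

Linear-predictor terms are centered/scaled once and for all
((age − 34)/8, log CD4 − 5.5) so that coefficients are interpretable and
the "correct" parametric learner coincides with the generating form.  An
optional quadratic-age term exists so that model-misspecification
scenarios can be constructed; it is absent from the shipped fixtures.
These marginals are stylized: the real cohort's covariate distributions
are not public, so the fixtures aim at the cohort's published margins,
not at its joint distribution.

`kisumu_like.cfg` freezes intercepts and the exposure coefficient
(−1.098, −2.597, +0.357 on the log-odds scale) calibrated once by Monte
Carlo over 4×10⁵ confounder draws to hit three targets simultaneously:
35% exposure prevalence, 8.7% outcome prevalence, and a true
ψ of +0.029.  `confounded.cfg` is a deliberately hard variant (strong
education/marital/gravidity effects on both A and Y, crude bias ≈ +0.010)
used for the double-robustness demonstrations, where the kisumu-like
fixture's near-negligible confounding would make bias undetectable.

True ψ is computed by exact enumeration over discrete confounder strata
whenever the outcome model uses only discrete terms, otherwise by Monte
Carlo averaging of expit(β_Y·x(W, 1)) − expit(β_Y·x(W, 0)); the
intercept-only case reduces to the closed form expit(c + b) − expit(c).

Observation layers:

- **MAR missingness**: each targeted confounder cell is deleted
  independently with probability expit of a logit over always-observed
  columns only (intercept, A, Y, age).  Conditioning on a
  missingness-eligible column is rejected at validation, so the
  mechanism is missing-at-random by construction.  Fixture defaults
  delete ~18% of CD4 nadir (outcome-dependent) and ~12% of education.
- **Exposure misclassification**: recorded A flips true A with rates
  1 − sensitivity (true users) and 1 − specificity (true non-users).
  The fraction of visits reporting COC is Beta(2, 2) for genuinely
  exposed recorded users and Beta(1, 6) for spurious reporters
  (recorded users who never truly used COC), then 0 for recorded
  non-users.  The low-mass false-positive distribution encodes the
  substantive assumption that spurious ever-use records arise from
  isolated visit entries; it is what gives the > 20%-of-visits
  sensitivity restriction its bias-repairing power.  Without false
  positives the restriction removes genuine users at random and cannot
  repair anything.
- Months observed ~ Gamma(shape 2, mean 24).

One integer seed drives everything; each stage (confounders, exposure,
outcome, visits, missingness, misclassification, each imputed dataset,
the bootstrap) uses an independent substream spawned from it, so a
cohort is byte-reproducible and stages are independently replayable.

## Chained multiple imputation

Missing confounders are completed by chained equations: initialize by
resampling observed values, then for a fixed number of cycles (default
10) refit each incomplete column's conditional model on the current
completed data and redraw the originally-missing cells.  Conditionals:
linear-normal on log CD4 (exponentiated back, preserving positivity);
linear-normal for gravidity with draws rounded and clipped to 0–12 (a
13-level multinomial would be too sparse at n ≈ 2500); multinomial
logistic for education; binary logistic for marital status.  Predictors
are A, Y, and the other confounders.  Coefficients are refit rather
than drawn from their posterior — a simplification of fully proper
imputation that slightly understates between-imputation variance but
makes every dataset a deterministic function of the seed.  Default
m = 10 datasets (pipeline tests and the acceptance script use m = 5 or
m = 2 to keep runtimes at desk scale; the pooling arithmetic is
identical at any m ≥ 2).

Pooling uses Rubin's rules: pooled estimate = mean, total variance =
within + (1 + 1/m)·between, t interval with df =
(m − 1)(1 + within/((1 + 1/m)·between))², collapsing to the normal
quantile when the between-imputation variance is zero.

## Nuisance-model selection

A discrete super learner picks, separately for the outcome and exposure
regressions, among four transparent logistic learners — intercept-only,
main effects, main effects + all pairwise interactions, main effects +
quadratic age — by V-fold (default 10) cross-validated negative
log-likelihood on a seed-fixed fold split, refitting the winner on the
full data; ties break toward the earlier library entry, and a learner
that fails to fit receives infinite loss.  The deliberately small
parametric library keeps selection reproducible and auditable while
still exercising the bias/variance logic of data-adaptive estimation;
it is not a substitute for a rich stacking library when real data
demand one.

## Estimators and numerics

- Propensities are truncated to [0.01, 0.99] by default (configurable);
  raw values outside the bounds are counted in the positivity report.
  Outcome predictions are floored away from {0, 1} at 1e−9 so logits
  stay finite.
- TMLE uses a single shared fluctuation parameter ε for both exposure
  levels, fit by an intercept-free logistic regression of Y on
  H = A/ĝ − (1−A)/(1−ĝ) with offset logit Q̂ (IRLS via statsmodels); the
  post-update score mean[H·(Y − Q*)] is zero to solver precision
  (≈ 1e−13 in practice, asserted at 1e−8).  The variance is the sample
  variance of the efficient influence curve divided by n, with a Wald
  95% CI.
- IPTW defaults to the normalized (Hájek) form — the weighted-population
  prevalence difference; the Horvitz–Thompson form is available behind
  `normalized=False` for testing.
- A degenerate outcome (all Y equal) returns ψ = 0 with a warning
  rather than failing, so pathological resamples and fixtures stay
  analyzable.
- Estimates are invariant to record order and column order (fold splits
  are positional, so cross-validated *selection* is tied to the given
  record order; the estimators themselves are not).

## Bootstrap and positivity diagnostics

The bootstrap resamples individual records (the cohort is
cross-sectional; no clustering) with replacement, rerunning the full
estimator — nuisance refit included — per resample; the selected learner
is held fixed within a bootstrap to keep replicates comparable.
Failed replicates (for example an empty exposure arm) are dropped and
counted, with a hard error beyond 20%.  Quantile 95% CIs use the
empirical 2.5/97.5 percentiles.  Bootstraps run inside each imputed
dataset; pooled bootstrap intervals apply the Rubin structure to the
per-imputation bootstrap means and variances, an interpretation the
results table labels as such rather than a quantile of a merged
replicate pool.

Positivity is inspected empirically: covariate combinations (age binned
to decades, CD4 nadir to the clinical <200 / 200–500 / >500 cells/µL
bands, other columns as-is) are flagged when either exposure arm is
empty; raw propensities outside the truncation bounds are counted; and
the bootstrap's center offset and skewness summarize whether
near-violations are distorting the sampling distribution.

## DAG module

d-separation is decided by the moralized-ancestral-graph criterion
(disconnection of x and y in the moral graph of An({x, y} ∪ z) after
deleting z), backdoor admissibility by the equivalent formulation
"no descendant of the exposure in Z, and X ⊥ Y | Z after deleting X's
outgoing edges", and minimal sufficient sets by exhaustive
inclusion-minimal search over subsets of non-descendants — adequate for
the identification-sized graphs this module is for, not for hundreds of
nodes.  The test suite checks the implementation against a brute-force
undirected-path enumerator (and networkx's independent implementation)
on every labeled DAG with up to five nodes.  Exogenous-noise (U) nodes
are ordinary nodes with no special semantics.  The "panel C" fixture's
wiring — W1→X, W3→X, X→Y, W3→Y, W2→Y, W1→W3, W2→W3 — is the canonical
structure reproducing all of that example's stated facts (the open
X–W3–Y backdoor, the new W1/W2 path opened by conditioning on W3, and
minimal sets {W1, W3}, {W2, W3}); fixture comments flag it as a
reconstruction, as is the stylized two-time-point graph.

## Sensitivity restriction

The restriction "≥ 6 months observed and COC reported at > 20% of
visits" is implemented as: keep records with months ≥ min_months and
(frac = 0 or frac > min_frac); recorded users with 0 < frac ≤ min_frac
are dropped as unreliably classified, never-reporters are retained
unconditionally.  This is the intersection of the two natural readings
(sample restriction vs exposure redefinition) and both thresholds are
configurable, so either pure reading is reachable.

## Problem sizes

Simulation-based checks use sizes chosen to make each effect detectable
without waste: n = 2519 (the emulated cohort size) with 200 replicates
for estimator consistency and TMLE coverage; n = 50 000 with 8
replicates for the double-robustness contrasts on the strongly
confounded fixture; 4×10⁵ Monte Carlo draws for true-ψ evaluation
(SE ≈ 5×10⁻⁴); B = 200 for the bootstrap symmetry check.  The
acceptance script uses 100 replicate cohorts and a 5-imputation,
B = 100 pipeline run.

## Known limitations

- The simulator draws confounders independently; real cohorts have
  correlated covariates, so propensity overlap is more benign here than
  in practice.  Passing positivity checks on fixtures says nothing
  about overlap in a real dataset.
- Imputation is not "proper" in the Bayesian sense (no posterior draw
  of coefficients); Rubin intervals are mildly anti-conservative under
  heavy missingness.
- No time-varying exposure, no visit-level records, no HPV-acquisition
  pathway: the simulator represents the single-time-point reduced model
  only.
- The learner library is intentionally small and parametric; the
  super-learner machinery generalizes, but no tree/ensemble learners
  are included.
- The two-ε TMLE variant, collaborative TMLE, stochastic interventions,
  and front-door/instrumental identification are out of scope.
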