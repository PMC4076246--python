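"""Cohort simulator: determinism, calibration, null effects, MAR
missingness, and exposure misclassification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from causalprev.synthetic_data import (
    ConfounderSpec,
    ScmParams,
    ScmParamsError,
    apply_mar_missingness,
    generate_cohort,
    load_params,
    misclassify_exposure,
    save_params,
    true_prevalence_difference,
)


class TestGenerateCohort:
    def test_same_seed_reproduces_identical_table(self, kisumu_params):
        first = generate_cohort(kisumu_params)
        second = generate_cohort(kisumu_params)
        pd.testing.assert_frame_equal(first, second)

    def test_different_seed_changes_table(self, kisumu_params):
        first = generate_cohort(kisumu_params)
        kisumu_params.seed += 1
        assert not first.equals(generate_cohort(kisumu_params))

    def test_null_exposure_effect_equalizes_outcome_law(self):
        """With a zero exposure coefficient the Y distribution must be
        identical in law across exposure strata (large-n frequencies)."""
        params = ScmParams(n=40_000, beta_A={"intercept": 0.0},
                           beta_Y={"intercept": -2.0, "marital": 0.8, "A": 0.0},
                           seed=11)
        table = generate_cohort(params)
        p1 = table.loc[table.A == 1, "Y"].mean()
        p0 = table.loc[table.A == 0, "Y"].mean()
        assert abs(p1 - p0) < 0.01

    def test_fixture_reproduces_cohort_prevalences(self, kisumu_params):
        """The shipped fixture targets ~35% exposure and ~8.7% outcome
        prevalence at the cohort size n = 2519."""
        table = generate_cohort(kisumu_params)
        assert len(table) == 2519
        assert abs(table["A"].mean() - 0.35) < 0.03
        assert abs(table["Y"].mean() - 0.087) < 0.02

    def test_frac_visits_zero_iff_nonuser(self, kisumu_params):
        table = generate_cohort(kisumu_params)
        assert (table.loc[table.A == 0, "frac_visits_coc"] == 0).all()
        assert (table.loc[table.A == 1, "frac_visits_coc"] > 0).all()

    def test_invalid_distribution_names_offending_field(self):
        params = ScmParams(n=5, confounder_spec=ConfounderSpec(education_probs=(0.5, 0.4)))
        with pytest.raises(ScmParamsError, match="education_probs"):
            generate_cohort(params)
        with pytest.raises(ScmParamsError, match="n must be"):
            generate_cohort(ScmParams(n=0))


class TestTruePrevalenceDifference:
    def test_zero_exposure_coefficient_gives_exact_null(self):
        params = ScmParams(beta_Y={"intercept": -1.0, "marital": 0.5, "A": 0.0})
        assert true_prevalence_difference(params) == 0.0

    def test_intercept_only_closed_form(self):
        c, b = -2.0, 0.7
        params = ScmParams(beta_Y={"intercept": c, "A": b})
        expected = expit(c + b) - expit(c)
        assert true_prevalence_difference(params) == pytest.approx(expected, abs=1e-12)

    def test_one_binary_confounder_matches_hand_enumeration(self):
        """Oracle: two-stratum weighted sum done by hand."""
        p_mar = 0.3
        params = ScmParams(
            confounder_spec=ConfounderSpec(marital_p=p_mar),
            beta_Y={"intercept": -1.5, "marital": 0.9, "A": 0.6})
        by_hand = sum(
            w * (expit(-1.5 + 0.9 * m + 0.6) - expit(-1.5 + 0.9 * m))
            for m, w in [(0, 1 - p_mar), (1, p_mar)])
        assert true_prevalence_difference(params) == pytest.approx(by_hand, abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        params = ScmParams(beta_Y={"intercept": -2.0, "education": 0.3,
                                   "gravidity": 0.1, "A": 0.5}, seed=3)
        exact = true_prevalence_difference(params)
        # force the Monte Carlo route by adding a continuous term with
        # zero coefficient (same ψ, different computation path)
        params_mc = ScmParams(beta_Y={**params.beta_Y, "log_cd4_c": 0.0}, seed=3)
        n_mc = 200_000
        mc = true_prevalence_difference(params_mc, n_mc)
        se = 0.5 / np.sqrt(n_mc)  # conservative bound on SE of a mean of [-1,1] terms
        assert abs(mc - exact) < 3 * se

    def test_fixture_truth_matches_calibration_target(self, kisumu_params):
        psi = true_prevalence_difference(kisumu_params, 400_000)
        assert psi == pytest.approx(0.029, abs=0.002)


class TestMarMissingness:
    def test_no_missingness_when_logits_are_minus_infinity(self, kisumu_params):
        table = generate_cohort(kisumu_params)
        kisumu_params.miss_spec = {"cd4_nadir": {"intercept": -np.inf}}
        out = apply_mar_missingness(table, kisumu_params)
        pd.testing.assert_frame_equal(out, table, check_dtype=False)

    def test_logit_zero_deletes_about_half(self, kisumu_params):
        kisumu_params.n = 2000
        table = generate_cohort(kisumu_params)
        kisumu_params.miss_spec = {"cd4_nadir": {"intercept": 0.0}}
        out = apply_mar_missingness(table, kisumu_params)
        assert abs(out["cd4_nadir"].isna().mean() - 0.5) < 0.05
        assert len(out) == len(table)

    def test_outcome_dependent_rates_match_configured_logits(self, kisumu_params):
        """Missingness on CD4 depending on Y: empirical stratum rates
        must track expit of the configured logits."""
        kisumu_params.n = 30_000
        table = generate_cohort(kisumu_params)
        kisumu_params.miss_spec = {"cd4_nadir": {"intercept": -1.5, "Y": 1.2}}
        out = apply_mar_missingness(table, kisumu_params)
        rate_y0 = out.loc[out.Y == 0, "cd4_nadir"].isna().mean()
        rate_y1 = out.loc[out.Y == 1, "cd4_nadir"].isna().mean()
        assert rate_y0 == pytest.approx(expit(-1.5), abs=0.02)
        assert rate_y1 == pytest.approx(expit(-0.3), abs=0.04)

    def test_exposure_and_outcome_never_missing(self, kisumu_params):
        table = generate_cohort(kisumu_params)
        kisumu_params.miss_spec = {"education": {"intercept": 3.0}}
        out = apply_mar_missingness(table, kisumu_params)
        assert not out["A"].isna().any() and not out["Y"].isna().any()

    def test_miss_spec_on_missable_predictor_rejected(self, kisumu_params):
        kisumu_params.miss_spec = {"cd4_nadir": {"education": 1.0}}
        with pytest.raises(ScmParamsError, match="MAR"):
            kisumu_params.validate()


class TestMisclassifyExposure:
    def test_perfect_sensitivity_and_specificity_is_identity(self, kisumu_params):
        table = generate_cohort(kisumu_params)
        out = misclassify_exposure(table, 1.0, 1.0, seed=5)
        assert (out["A"] == table["true_A"]).all()

    def test_false_negative_rate_matches_sensitivity(self, kisumu_params):
        kisumu_params.n = 10_000
        table = generate_cohort(kisumu_params)
        out = misclassify_exposure(table, 0.7, 1.0, seed=5)
        true_exposed = table["true_A"] == 1
        n_flipped = int(((out["A"] == 0) & true_exposed).sum())
        expected = 0.3 * true_exposed.sum()
        assert abs(n_flipped - expected) < 4 * np.sqrt(0.3 * 0.7 * true_exposed.sum())

    def test_frac_visits_regenerated_consistently(self, kisumu_params):
        table = generate_cohort(kisumu_params)
        out = misclassify_exposure(table, 0.7, 0.9, seed=5)
        assert (out.loc[out.A == 0, "frac_visits_coc"] == 0).all()
        assert (out.loc[out.A == 1, "frac_visits_coc"] > 0).all()

    def test_requires_latent_truth(self, kisumu_params):
        table = generate_cohort(kisumu_params).drop(columns=["true_A"])
        with pytest.raises(ValueError, match="true_A"):
            misclassify_exposure(table, 0.9, 0.9, seed=1)


def test_params_config_round_trip(tmp_path, kisumu_params):
    path = tmp_path / "params.cfg"
    save_params(kisumu_params, path)
    loaded = load_params(path)
    assert loaded == kisumu_params
    pd.testing.assert_frame_equal(generate_cohort(loaded), generate_cohort(kisumu_params))
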