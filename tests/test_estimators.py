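"""Estimators of ψ: exact identities, hand-worked cases, learner
selection, and agreement with nonparametric standardization."""

import numpy as np
import pandas as pd
import pytest

from causalprev.estimators import (
    EstimationError,
    LearnerLibrary,
    OutcomeFit,
    PositivityError,
    PropensityFit,
    discrete_super_learner,
    fit_learner,
    g_compute,
    iptw_estimate,
    stabilized_weights,
    tmle_estimate,
)
from causalprev.synthetic_data import generate_cohort
from oracles import discrete_cohort, saturated_fits, standardization


def _constant_outcome_fit(p):
    return OutcomeFit("constant", lambda a, t: np.full(len(t), p))


class TestDiscreteSuperLearner:
    def test_single_learner_library_returns_it(self, kisumu_cohort):
        lib = LearnerLibrary(learners=("quadratic_age",), v_folds=3)
        fit = discrete_super_learner(kisumu_cohort, "outcome", lib, seed=0)
        assert fit.learner_id == "quadratic_age"

    def test_correct_form_selected_on_main_effects_data(self, kisumu_params):
        """Data generated from a main-effects logistic at n = 5000:
        cross-validation should pick the main-effects learner."""
        kisumu_params.n = 5000
        wins = 0
        for rep in range(5):
            kisumu_params.seed = 40 + rep
            table = generate_cohort(kisumu_params)
            fit = discrete_super_learner(table, "outcome", LearnerLibrary(v_folds=5),
                                         seed=rep)
            wins += fit.learner_id == "main_effects"
        assert wins >= 3

    def test_intercept_selected_when_outcome_is_pure_noise(self, rng):
        wins = 0
        for rep in range(5):
            table = discrete_cohort(np.random.default_rng(rep), n=3000,
                                    p_y=((0.1, 0.1), (0.1, 0.1)))
            fit = discrete_super_learner(table, "outcome",
                                         LearnerLibrary(v_folds=5), seed=rep)
            wins += fit.learner_id == "intercept"
        assert wins >= 3

    def test_fold_split_is_seed_fixed(self, kisumu_cohort):
        a = discrete_super_learner(kisumu_cohort, "exposure", seed=3)
        b = discrete_super_learner(kisumu_cohort, "exposure", seed=3)
        assert a.learner_id == b.learner_id


class TestGComputation:
    def test_fit_ignoring_exposure_gives_exact_null(self, kisumu_cohort):
        result = g_compute(kisumu_cohort, _constant_outcome_fit(0.2))
        assert result.psi == 0.0

    def test_saturated_fit_equals_nonparametric_standardization(self, rng):
        table = discrete_cohort(rng)
        q_fn, _ = saturated_fits(table)
        result = g_compute(table, OutcomeFit("saturated", q_fn))
        assert result.psi == pytest.approx(standardization(table, ["marital"]), abs=1e-12)

    def test_recovers_truth_with_correct_model_at_large_n(self, kisumu_params):
        kisumu_params.n = 50_000
        table = generate_cohort(kisumu_params)
        result = g_compute(table, fit_learner(table, "outcome", "main_effects"))
        # ψ-scale sampling SE at n = 50 000 is ≈ 0.0015
        assert result.psi == pytest.approx(0.029, abs=3 * 0.0015)


class TestStabilizedWeights:
    def test_randomized_exposure_limit_gives_unit_weights(self, kisumu_cohort):
        p = kisumu_cohort["A"].mean()
        fit = PropensityFit("constant", lambda t: np.full(len(t), p))
        w = stabilized_weights(kisumu_cohort, fit)
        assert np.allclose(w, 1.0)

    def test_direct_formula(self):
        # empirical P(A=1) = 7/20 = 0.35; exposed record with g = 0.1
        # must get weight 0.35/0.1 = 3.5
        a = np.array([1] * 7 + [0] * 13)
        table = pd.DataFrame({"A": a, "Y": 0})
        fit = PropensityFit("constant", lambda t: np.full(len(t), 0.1))
        w = stabilized_weights(table, fit)
        assert w[0] == pytest.approx(0.35 / 0.1)
        assert w[-1] == pytest.approx(0.65 / 0.9)

    def test_mean_weight_near_one_under_correct_model(self, kisumu_params):
        kisumu_params.n = 5000
        table = generate_cohort(kisumu_params)
        w = stabilized_weights(table, fit_learner(table, "exposure", "main_effects"))
        assert abs(w.mean() - 1.0) < 0.05

    def test_untruncated_degenerate_propensity_raises(self, kisumu_cohort):
        fit = PropensityFit("bad", lambda t: np.zeros(len(t)), truncation_bounds=None)
        with pytest.raises(PositivityError, match="truncation_bounds"):
            stabilized_weights(kisumu_cohort, fit)


class TestIptw:
    def test_unit_weights_reduce_to_crude_difference(self, kisumu_cohort):
        crude = (kisumu_cohort.loc[kisumu_cohort.A == 1, "Y"].mean()
                 - kisumu_cohort.loc[kisumu_cohort.A == 0, "Y"].mean())
        result = iptw_estimate(kisumu_cohort, np.ones(len(kisumu_cohort)))
        assert result.psi == pytest.approx(crude, abs=1e-12)

    def test_hand_worked_four_record_case(self):
        table = pd.DataFrame({"A": [1, 1, 0, 0], "Y": [1, 0, 1, 0]})
        w = np.array([2.0, 1.0, 1.0, 3.0])
        result = iptw_estimate(table, w)
        assert result.psi == pytest.approx(2 / 3 - 1 / 4, abs=1e-12)

    def test_horvitz_thompson_form_differs_from_hajek(self):
        table = pd.DataFrame({"A": [1, 1, 0, 0], "Y": [1, 0, 1, 0]})
        w = np.array([2.0, 1.0, 1.0, 3.0])
        ht = iptw_estimate(table, w, normalized=False)
        assert ht.psi == pytest.approx(2 / 4 - 1 / 4, abs=1e-12)

    def test_empty_arm_raises(self):
        table = pd.DataFrame({"A": [1, 1], "Y": [1, 0]})
        with pytest.raises(EstimationError, match="arm"):
            iptw_estimate(table, np.ones(2))


class TestTmle:
    def test_zero_fluctuation_when_initial_fit_solves_score(self, rng):
        """A saturated Q0 already solves the score equation, so ε̂ = 0 and
        TMLE coincides with g-computation."""
        table = discrete_cohort(rng)
        q_fn, g_fn = saturated_fits(table)
        q0 = OutcomeFit("saturated", q_fn)
        gfit = PropensityFit("saturated", g_fn)
        tmle = tmle_estimate(table, q0, gfit)
        gcomp = g_compute(table, q0)
        assert tmle.diagnostics["epsilon"] == pytest.approx(0.0, abs=1e-7)
        assert tmle.psi == pytest.approx(gcomp.psi, abs=1e-8)

    def test_score_equation_solved_after_update(self, kisumu_cohort):
        q0 = fit_learner(kisumu_cohort, "outcome", "intercept")
        gfit = fit_learner(kisumu_cohort, "exposure", "main_effects")
        result = tmle_estimate(kisumu_cohort, q0, gfit)
        assert abs(result.diagnostics["score"]) < 1e-8
        assert result.ci_low <= result.psi <= result.ci_high

    def test_all_three_estimators_match_standardization_when_saturated(self, rng):
        table = discrete_cohort(rng)
        q_fn, g_fn = saturated_fits(table)
        q0 = OutcomeFit("saturated", q_fn)
        gfit = PropensityFit("saturated", g_fn, truncation_bounds=(1e-12, 1 - 1e-12))
        oracle = standardization(table, ["marital"])
        assert g_compute(table, q0).psi == pytest.approx(oracle, abs=1e-10)
        assert iptw_estimate(table, stabilized_weights(table, gfit)).psi == \
            pytest.approx(oracle, abs=1e-10)
        assert tmle_estimate(table, q0, gfit).psi == pytest.approx(oracle, abs=1e-10)


class TestDegenerateAndInvariance:
    def test_degenerate_outcome_returns_null_with_warning(self, kisumu_cohort):
        table = kisumu_cohort.copy()
        table["Y"] = 0
        with pytest.warns(UserWarning, match="degenerate"):
            result = g_compute(table, _constant_outcome_fit(0.5))
        assert result.psi == 0.0 and result.diagnostics["degenerate_outcome"]

    def test_estimates_invariant_to_record_and_column_order(self, kisumu_cohort):
        shuffled = kisumu_cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled = shuffled[list(shuffled.columns[::-1])]

        def run(t):
            q = fit_learner(t, "outcome", "main_effects")
            g = fit_learner(t, "exposure", "main_effects")
            return (g_compute(t, q).psi,
                    iptw_estimate(t, stabilized_weights(t, g)).psi,
                    tmle_estimate(t, q, g).psi)

        for orig, perm in zip(run(kisumu_cohort), run(shuffled)):
            assert orig == pytest.approx(perm, abs=1e-6)
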