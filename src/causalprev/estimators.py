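"""Semi-parametric estimators of the marginal prevalence difference.

Target parameter: ψ = E[Y(1)] − E[Y(0)], the change in outcome
prevalence if the whole cohort were exposed versus unexposed.  Three
estimators are provided, each built from nuisance regressions selected
by a discrete super learner (V-fold cross-validation over a small fixed
library of logistic learners, negative log-likelihood loss):

g-computation
    Fit an outcome regression Q(A, W) = P(Y=1 | A, W), predict for every
    record with exposure forced to 1 and to 0, and average the
    difference.  Consistent when Q is correctly specified.

stabilized IPTW
    Fit a propensity g(W) = P(A=1 | W); weight exposed records by
    P(A=1)/g and unexposed by P(A=0)/(1−g), then take the difference of
    weighted (Hájek) outcome means.  Consistent when g is correct.

TMLE
    Update the initial Q along a one-dimensional logistic fluctuation
    with clever covariate H(A, W) = A/g − (1−A)/(1−g), so the updated
    Q* solves the efficient influence-curve equation; ψ is the
    g-computation functional of Q*.  Doubly robust: consistent if either
    Q or g is correct, with a closed-form influence-curve variance.

Propensities are truncated into [0.01, 0.99] by default as a practical
positivity guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .synthetic_data import AGE_CENTER, AGE_SCALE, LOG_CD4_CENTER

__all__ = [
    "LearnerLibrary",
    "OutcomeFit",
    "PropensityFit",
    "EstimateResult",
    "EstimationError",
    "PositivityError",
    "discrete_super_learner",
    "fit_learner",
    "g_compute",
    "stabilized_weights",
    "iptw_estimate",
    "tmle_estimate",
]

DEFAULT_G_BOUNDS = (0.01, 0.99)
_Q_FLOOR = 1e-9  # keeps logit(Q) finite in the fluctuation
_LEARNER_IDS = ("intercept", "main_effects", "interactions", "quadratic_age")


class EstimationError(RuntimeError):
    """An estimator could not produce a valid estimate."""


class PositivityError(EstimationError):
    """Estimated propensities reached 0 or 1; see truncation_bounds."""


@dataclass
class LearnerLibrary:
    """Ordered candidate learners for the discrete super learner.

    The four built-in learners are transparent logistic regressions on
    the standardized confounder terms: intercept-only; main effects;
    main effects plus all pairwise interactions; main effects plus a
    quadratic age term.  Cross-validated negative log-likelihood picks
    the winner; ties break toward the earlier library entry.
    """

    learners: tuple = _LEARNER_IDS
    v_folds: int = 10

    def validate(self) -> None:
        if len(self.learners) < 1:
            raise ValueError("LearnerLibrary requires at least one learner")
        if self.v_folds < 2:
            raise ValueError("LearnerLibrary.v_folds must be >= 2")
        unknown = set(self.learners) - set(_LEARNER_IDS)
        if unknown:
            raise ValueError(f"unknown learners: {sorted(unknown)}")


@dataclass
class OutcomeFit:
    """Fitted outcome regression: ``predict(a, table)`` returns
    P(Y=1 | A=a, W) in (0, 1) for every record, for a scalar or
    per-record exposure assignment."""

    learner_id: str
    _predict: Callable

    def predict(self, a, table: pd.DataFrame) -> np.ndarray:
        p = np.asarray(self._predict(a, table), dtype=float)
        return np.clip(p, _Q_FLOOR, 1.0 - _Q_FLOOR)


@dataclass
class PropensityFit:
    """Fitted exposure model: ``g(table)`` returns P(A=1 | W) truncated
    into ``truncation_bounds``; ``g_raw`` skips truncation (used by
    positivity diagnostics)."""

    learner_id: str
    _predict: Callable
    truncation_bounds: tuple = DEFAULT_G_BOUNDS

    def g_raw(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray(self._predict(table), dtype=float)

    def g(self, table: pd.DataFrame) -> np.ndarray:
        raw = self.g_raw(table)
        if self.truncation_bounds is None:
            return raw
        lo, hi = self.truncation_bounds
        return np.clip(raw, lo, hi)


@dataclass
class EstimateResult:
    """Point estimate of ψ with optional variance/CI and diagnostics."""

    psi: float
    method: str
    variance: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# learner design matrices

def _base_terms(table: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        (table["age"].to_numpy(float) - AGE_CENTER) / AGE_SCALE,
        table["education"].to_numpy(float),
        table["marital"].to_numpy(float),
        table["gravidity"].to_numpy(float),
        np.log(table["cd4_nadir"].to_numpy(float)) - LOG_CD4_CENTER,
    ])


def _learner_design(table: pd.DataFrame, learner_id: str,
                    a: np.ndarray | int | None = None) -> np.ndarray:
    x = _base_terms(table)
    if a is not None:
        a_col = np.broadcast_to(np.asarray(a, dtype=float), (len(table),))
        x = np.column_stack([a_col, x])
    if learner_id == "main_effects":
        return x
    if learner_id == "quadratic_age":
        age_idx = 1 if a is not None else 0
        return np.column_stack([x, x[:, age_idx] ** 2])
    if learner_id == "interactions":
        k = x.shape[1]
        pairs = [x[:, i] * x[:, j] for i in range(k) for j in range(i + 1, k)]
        return np.column_stack([x] + pairs)
    raise ValueError(f"unknown learner {learner_id!r}")


def fit_learner(table: pd.DataFrame, target: str, learner_id: str) -> OutcomeFit | PropensityFit:
    """Fit one library learner for ``target`` ('outcome' or 'exposure')
    on the full table and wrap it as the corresponding fit object."""
    if target not in ("outcome", "exposure"):
        raise ValueError("target must be 'outcome' or 'exposure'")
    ycol = "Y" if target == "outcome" else "A"
    y = table[ycol].to_numpy(int)
    if learner_id == "intercept":
        p_hat = float(np.clip(y.mean(), _Q_FLOOR, 1 - _Q_FLOOR))
        if target == "outcome":
            return OutcomeFit("intercept", lambda a, t, p=p_hat: np.full(len(t), p))
        return PropensityFit("intercept", lambda t, p=p_hat: np.full(len(t), p))
    with_a = target == "outcome"
    x = _learner_design(table, learner_id, table["A"].to_numpy(int) if with_a else None)
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    if target == "outcome":
        def predict(a, t, m=model, lid=learner_id):
            return m.predict_proba(_learner_design(t, lid, a))[:, 1]
        return OutcomeFit(learner_id, predict)

    def predict_g(t, m=model, lid=learner_id):
        return m.predict_proba(_learner_design(t, lid))[:, 1]
    return PropensityFit(learner_id, predict_g)


def _cv_loss(table: pd.DataFrame, target: str, learner_id: str,
             v_folds: int, seed: int) -> float:
    ycol = "Y" if target == "outcome" else "A"
    y_all = table[ycol].to_numpy(int)
    folds = KFold(n_splits=v_folds, shuffle=True, random_state=seed)
    losses = []
    for train_idx, test_idx in folds.split(table):
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        try:
            fit = fit_learner(train, target, learner_id)
        except Exception:
            return np.inf
        if target == "outcome":
            p = fit.predict(test["A"].to_numpy(int), test)
        else:
            p = np.clip(fit.g_raw(test), _Q_FLOOR, 1 - _Q_FLOOR)
        y = y_all[test_idx]
        losses.append(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean(losses))


def discrete_super_learner(table: pd.DataFrame, target: str,
                           lib: LearnerLibrary | None = None,
                           seed: int = 0) -> OutcomeFit | PropensityFit:
    """Select the library learner with minimal V-fold cross-validated
    negative log-likelihood (seed-fixed folds) and refit it on the full
    table.  A learner that fails to fit gets infinite loss; if all fail,
    an :class:`EstimationError` is raised."""
    lib = lib or LearnerLibrary()
    lib.validate()
    if len(lib.learners) == 1:
        return fit_learner(table, target, lib.learners[0])
    losses = [_cv_loss(table, target, lid, lib.v_folds, seed) for lid in lib.learners]
    best = int(np.argmin(losses))  # argmin takes the first minimum: library-order ties
    if not np.isfinite(losses[best]):
        raise EstimationError(f"all {target} learners failed cross-validation")
    return fit_learner(table, target, lib.learners[best])


# ---------------------------------------------------------------------------
# estimators

def _degenerate_result(table: pd.DataFrame, method: str) -> EstimateResult | None:
    y = table["Y"].to_numpy(int)
    if y.min() == y.max():
        warnings.warn(f"degenerate outcome (all Y = {y[0]}); {method} returns psi = 0")
        return EstimateResult(psi=0.0, method=method,
                              diagnostics={"degenerate_outcome": True})
    return None


def g_compute(table: pd.DataFrame, fit: OutcomeFit) -> EstimateResult:
    """Substitution estimator: ψ̂ = mean[Q̂(1, W)] − mean[Q̂(0, W)].

    Variance is left unset; it is supplied by the bootstrap.
    """
    degenerate = _degenerate_result(table, "gcomp")
    if degenerate is not None:
        return degenerate
    psi = float(fit.predict(1, table).mean() - fit.predict(0, table).mean())
    return EstimateResult(psi=psi, method="gcomp",
                          diagnostics={"learner": fit.learner_id})


def stabilized_weights(table: pd.DataFrame, fit: PropensityFit) -> np.ndarray:
    """Stabilized inverse-probability weights: P̂(A=1)/ĝ for the exposed,
    P̂(A=0)/(1−ĝ) for the unexposed, with P̂ the empirical prevalence."""
    a = table["A"].to_numpy(int)
    g = fit.g(table)
    if np.any(g <= 0) or np.any(g >= 1):
        raise PositivityError(
            "propensity reached 0 or 1; set PropensityFit.truncation_bounds "
            "to a proper sub-interval of (0, 1)")
    p1 = a.mean()
    return np.where(a == 1, p1 / g, (1.0 - p1) / (1.0 - g))


def iptw_estimate(table: pd.DataFrame, weights: np.ndarray,
                  normalized: bool = True) -> EstimateResult:
    """Weighted prevalence difference between exposure arms.

    Default is the normalized (Hájek) form — each arm's weighted outcome
    mean uses that arm's total weight; ``normalized=False`` gives the
    Horvitz–Thompson form dividing by n instead.  Variance is supplied
    by the bootstrap.
    """
    degenerate = _degenerate_result(table, "iptw")
    if degenerate is not None:
        return degenerate
    a = table["A"].to_numpy(int)
    y = table["Y"].to_numpy(int)
    w = np.asarray(weights, dtype=float)
    w1, w0 = w * (a == 1), w * (a == 0)
    if w1.sum() == 0 or w0.sum() == 0:
        raise EstimationError("an exposure arm has zero total weight")
    if normalized:
        psi = (w1 @ y) / w1.sum() - (w0 @ y) / w0.sum()
    else:
        n = len(y)
        psi = (w1 @ y) / n - (w0 @ y) / n
    return EstimateResult(psi=float(psi), method="iptw",
                          diagnostics={"mean_weight": float(w.mean())})


def tmle_estimate(table: pd.DataFrame, q0: OutcomeFit,
                  gfit: PropensityFit) -> EstimateResult:
    """Targeted maximum likelihood estimate of ψ with influence-curve CI.

    The initial outcome fit is fluctuated along the one-dimensional
    logistic submodel logit Q* = logit Q0 + ε·H with clever covariate
    H = A/ĝ − (1−A)/(1−ĝ); ε̂ is the MLE (logistic regression of Y on H
    with offset logit Q0 and no intercept), so Q* solves the score
    equation mean[H·(Y − Q*)] = 0.  The Wald 95% CI uses the sample
    variance of the efficient influence curve divided by n.
    """
    degenerate = _degenerate_result(table, "tmle")
    if degenerate is not None:
        return degenerate
    a = table["A"].to_numpy(int)
    y = table["Y"].to_numpy(int)
    n = len(y)
    g = gfit.g(table)
    h_obs = a / g - (1 - a) / (1 - g)
    q0_obs = q0.predict(a, table)
    q0_1 = q0.predict(1, table)
    q0_0 = q0.predict(0, table)
    try:
        fluct = sm.GLM(y, h_obs[:, None], family=sm.families.Binomial(),
                       offset=logit(q0_obs)).fit()
        eps = float(fluct.params[0])
    except Exception as exc:  # pragma: no cover - solver pathology
        raise EstimationError(f"TMLE fluctuation failed to converge: {exc}") from exc
    q1 = expit(logit(q0_1) + eps / g)
    q0_star = expit(logit(q0_0) - eps / (1 - g))
    q_obs = np.where(a == 1, q1, q0_star)
    psi = float(q1.mean() - q0_star.mean())
    ic = h_obs * (y - q_obs) + q1 - q0_star - psi
    variance = float(ic.var(ddof=0) / n)
    half = 1.959963984540054 * np.sqrt(variance)
    return EstimateResult(
        psi=psi, method="tmle", variance=variance,
        ci_low=psi - half, ci_high=psi + half,
        diagnostics={
            "epsilon": eps,
            "score": float(np.mean(h_obs * (y - q_obs))),
            "q_learner": q0.learner_id,
            "g_learner": gfit.learner_id,
        })
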