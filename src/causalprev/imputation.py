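"""Chained multiple imputation of missing confounders and Rubin's-rule
pooling of estimates across completed datasets.

Missing confounder cells are filled by multiple imputation with chained
equations: each incomplete column is regressed on the exposure, the
outcome, and the other confounders, and missing cells are replaced by
draws from the fitted conditional; the sweep over columns is iterated a
fixed number of cycles per dataset.  Conditional models are logistic for
binary targets, multinomial logistic for categorical targets, and
linear-normal for continuous targets (CD4 nadir is modeled on the log
scale to respect positivity; gravidity draws are rounded and clipped to
the 0–12 support).  Coefficients are refit at each cycle rather than
drawn from their posterior — a deliberate simplification of fully proper
imputation that keeps every dataset a deterministic function of the seed.

Estimates computed on the m completed datasets are combined with Rubin's
rules: pooled point estimate = mean; total variance = within-imputation
mean variance + (1 + 1/m) × between-imputation variance; interval from a
t distribution with Rubin's degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, LogisticRegression

from .cohort import CONFOUNDERS, MISSABLE

__all__ = ["ImputationConfig", "PooledResult", "chained_impute", "rubins_rule"]

#: conditional-model family per missable column
_FAMILY = {
    "education": "categorical",
    "marital": "binary",
    "gravidity": "count",
    "cd4_nadir": "lognormal",
}


@dataclass
class ImputationConfig:
    """Settings for chained imputation: ``m`` completed datasets,
    ``n_cycles`` sweeps per dataset, and an optional predictor matrix
    mapping each imputed column to its predictor columns (default: the
    exposure, the outcome, and every other confounder)."""

    m: int = 10
    n_cycles: int = 10
    seed: int = 0
    predictor_matrix: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.m < 2:
            raise ValueError("ImputationConfig.m must be >= 2")
        if self.n_cycles < 1:
            raise ValueError("ImputationConfig.n_cycles must be >= 1")


@dataclass
class PooledResult:
    """Rubin's-rule combination of estimates across imputed datasets."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    ci_low: float
    ci_high: float
    m: int
    df: float


def _predictors_for(col: str, cfg: ImputationConfig) -> list:
    if col in cfg.predictor_matrix:
        return list(cfg.predictor_matrix[col])
    return [c for c in CONFOUNDERS if c != col] + ["A", "Y"]


def _design(table: pd.DataFrame, cols: list) -> np.ndarray:
    x = np.empty((len(table), len(cols)))
    for j, c in enumerate(cols):
        v = table[c].to_numpy(float)
        if c == "cd4_nadir":
            v = np.log(v)
        x[:, j] = v
    return x


def _impute_column(work: pd.DataFrame, col: str, miss: np.ndarray,
                   predictors: list, rng: np.random.Generator) -> None:
    """Refit the conditional model for ``col`` on currently-complete data
    and redraw the originally-missing cells in place."""
    x = _design(work, predictors)
    obs = ~miss
    family = _FAMILY[col]
    if family in ("lognormal", "count"):
        y = work[col].to_numpy(float)
        target = np.log(y) if family == "lognormal" else y
        model = LinearRegression().fit(x[obs], target[obs])
        resid = target[obs] - model.predict(x[obs])
        dof = max(obs.sum() - len(predictors) - 1, 1)
        sigma = float(np.sqrt((resid ** 2).sum() / dof))
        draw = model.predict(x[miss]) + rng.normal(0.0, sigma, size=int(miss.sum()))
        if family == "lognormal":
            work.loc[miss, col] = np.exp(draw)
        else:
            work.loc[miss, col] = np.clip(np.round(draw), 0, 12)
    else:
        y = work[col].to_numpy(float).astype(int)
        classes = np.unique(y[obs])
        if len(classes) < 2:  # degenerate observed column: impute the constant
            work.loc[miss, col] = classes[0]
            return
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        model.fit(x[obs], y[obs])
        probs = model.predict_proba(x[miss])
        cum = probs.cumsum(axis=1)
        u = rng.random((int(miss.sum()), 1))
        idx = (u > cum).sum(axis=1)
        work.loc[miss, col] = model.classes_[idx]


def chained_impute(table: pd.DataFrame, cfg: ImputationConfig) -> list:
    """Produce ``cfg.m`` completed copies of ``table`` by chained
    equations; observed cells are never altered.

    Raises if missingness occurs outside the confounder columns or if a
    column with missing cells has no observed value to learn from.
    """
    cfg.validate()
    bad = [c for c in table.columns
           if c not in MISSABLE and table[c].isna().any()]
    if bad:
        raise ValueError(f"missingness outside imputable confounder columns: {bad}")
    targets = [c for c in MISSABLE if c in table.columns and table[c].isna().any()]
    if not targets:
        return [table.copy() for _ in range(cfg.m)]
    for col in targets:
        if table[col].notna().sum() == 0:
            raise ValueError(f"column {col!r} is entirely missing and cannot be imputed")

    miss_masks = {c: table[c].isna().to_numpy() for c in targets}
    completed = []
    for k in range(cfg.m):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(100 + k,)))
        work = table.copy()
        for col in targets:  # initialize by resampling observed values
            obs_vals = work.loc[~miss_masks[col], col].to_numpy()
            work.loc[miss_masks[col], col] = rng.choice(obs_vals, size=int(miss_masks[col].sum()))
        for _ in range(cfg.n_cycles):
            for col in targets:
                _impute_column(work, col, miss_masks[col], _predictors_for(col, cfg), rng)
        completed.append(work)
    return completed


def rubins_rule(estimates, variances, alpha: float = 0.05) -> PooledResult:
    """Pool m ≥ 2 per-dataset estimates and variances by Rubin's rules.

    total_var = within + (1 + 1/m)·between; the interval uses Rubin's
    degrees of freedom (m−1)(1 + within/((1+1/m)·between))², collapsing
    to the normal quantile when the between-imputation variance is zero.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-d sequences")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin's rules require at least 2 imputed datasets")
    if (u < 0).any():
        raise ValueError("variances must be non-negative")
    estimate = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        df = np.inf
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = crit * np.sqrt(total)
    return PooledResult(estimate=estimate, within_var=within, between_var=between,
                        total_var=total, ci_low=estimate - half, ci_high=estimate + half,
                        m=m, df=float(df))
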