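"""Bootstrap inference, positivity diagnostics, and pooling across
imputations.

Variance for g-computation and IPTW comes from a nonparametric bootstrap
(records resampled with replacement, the full estimator — including
nuisance-model refitting — rerun per resample) with a quantile 95% CI.
TMLE carries its own influence-curve variance but can be bootstrapped
the same way as a cross-check.

Positivity is inspected empirically: observed covariate combinations
(continuous columns pre-binned: age into decades, CD4 nadir into
<200 / 200–500 / >500 cells/µL) are flagged when they contain no exposed
or no unexposed record, raw propensities outside the truncation bounds
are counted, and the symmetry of the bootstrap distribution around the
point estimate is reported — an asymmetric, off-center bootstrap is the
practical signature of near-positivity violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimateResult, PropensityFit
from .imputation import PooledResult, rubins_rule

__all__ = [
    "BootstrapResult",
    "PositivityReport",
    "InferenceError",
    "bootstrap",
    "positivity_report",
    "pool_pipeline",
    "bin_strata",
]

#: clinically conventional CD4 nadir cut-points (cells/µL)
CD4_BINS = (200.0, 500.0)
CD4_LABELS = ("<200", "200-500", ">500")


class InferenceError(RuntimeError):
    """Bootstrap failure rate exceeded the tolerated threshold."""


@dataclass
class BootstrapResult:
    """Empirical distribution of ψ over bootstrap resamples."""

    replicates: np.ndarray
    boot_mean: float
    quantile_ci: tuple
    seed: int
    n_requested: int
    n_failed: int = 0

    @property
    def boot_se(self) -> float:
        return float(np.std(self.replicates, ddof=1))


@dataclass
class PositivityReport:
    """Empirical positivity and bootstrap-symmetry diagnostics."""

    flagged_strata: list = field(default_factory=list)
    n_strata: int = 0
    g_extremes: int = 0
    symmetry: tuple = (np.nan, np.nan)  # (boot_mean − point, skewness)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable table of flagged strata."""
        return pd.DataFrame(self.flagged_strata)


def bootstrap(table: pd.DataFrame,
              estimator: Callable[[pd.DataFrame], EstimateResult],
              B: int = 200, seed: int = 0,
              max_failure_rate: float = 0.2) -> BootstrapResult:
    """Resample ``B`` cohorts of n records with replacement and rerun the
    full estimator on each.

    Replicates where the estimator raises (for example an empty exposure
    arm in a rare-outcome resample) are dropped and counted; more than
    ``max_failure_rate`` failures is an :class:`InferenceError`.
    Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("bootstrap requires B >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    n = len(table)
    reps, failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resample = table.iloc[idx].reset_index(drop=True)
        try:
            result = estimator(resample)
            reps.append(result.psi if isinstance(result, EstimateResult) else float(result))
        except Exception:
            failed += 1
    if failed > max_failure_rate * B:
        raise InferenceError(f"{failed}/{B} bootstrap replicates failed")
    reps = np.asarray(reps, dtype=float)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(replicates=reps, boot_mean=float(reps.mean()),
                           quantile_ci=(float(lo), float(hi)), seed=seed,
                           n_requested=B, n_failed=failed)


def bin_strata(table: pd.DataFrame, strata_cols: Sequence[str]) -> pd.DataFrame:
    """Discretize the requested stratum columns: age to decades, CD4
    nadir to the conventional <200 / 200–500 / >500 bands; already
    discrete columns pass through unchanged."""
    out = pd.DataFrame(index=table.index)
    for col in strata_cols:
        if col == "age":
            out[col] = (table["age"] // 10 * 10).astype(int).astype(str) + "s"
        elif col == "cd4_nadir":
            out[col] = pd.cut(table["cd4_nadir"], [0, *CD4_BINS, np.inf],
                              labels=CD4_LABELS, right=False).astype(str)
        else:
            out[col] = table[col]
    return out


def positivity_report(table: pd.DataFrame,
                      gfit: PropensityFit | None = None,
                      boot: BootstrapResult | None = None,
                      point: EstimateResult | None = None,
                      strata_cols: Sequence[str] = ("education", "marital", "gravidity"),
                      ) -> PositivityReport:
    """Flag observed covariate combinations with zero exposed or zero
    unexposed records, count raw propensities outside the truncation
    bounds, and summarize bootstrap symmetry around the point estimate."""
    strata = bin_strata(table, strata_cols)
    grouped = table.assign(**{c: strata[c] for c in strata.columns}).groupby(
        list(strata_cols), observed=True)["A"]
    counts = grouped.agg(n="size", n_exposed="sum")
    counts["n_unexposed"] = counts["n"] - counts["n_exposed"]
    flagged = []
    for key, row in counts.iterrows():
        if row["n_exposed"] == 0 or row["n_unexposed"] == 0:
            key = key if isinstance(key, tuple) else (key,)
            desc = dict(zip(strata_cols, key))
            desc.update(n=int(row["n"]), n_exposed=int(row["n_exposed"]),
                        n_unexposed=int(row["n_unexposed"]))
            flagged.append(desc)
    g_extremes = 0
    if gfit is not None and gfit.truncation_bounds is not None:
        raw = gfit.g_raw(table)
        lo, hi = gfit.truncation_bounds
        g_extremes = int(((raw < lo) | (raw > hi)).sum())
    symmetry = (np.nan, np.nan)
    if boot is not None and point is not None:
        skew = float(stats.skew(boot.replicates)) if len(boot.replicates) > 2 else np.nan
        symmetry = (float(boot.boot_mean - point.psi), skew)
    return PositivityReport(flagged_strata=flagged, n_strata=len(counts),
                            g_extremes=g_extremes, symmetry=symmetry)


def pool_pipeline(per_imputation_results: Sequence[tuple]) -> PooledResult:
    """Combine (ψ, variance) pairs from the m imputed datasets with
    Rubin's rules; for bootstrap-variance estimators the per-imputation
    variance is the bootstrap replicate variance."""
    if len(per_imputation_results) < 2:
        raise ValueError("pooling requires results from at least 2 imputed datasets")
    estimates = [r[0] for r in per_imputation_results]
    variances = [r[1] for r in per_imputation_results]
    return rubins_rule(estimates, variances)
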