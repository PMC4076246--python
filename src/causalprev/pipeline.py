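"""Config-driven orchestration: crude description, sensitivity
restriction, and the full main + sensitivity estimation pipeline.

A run executes, in order: cohort load or simulation (women aged 50+ are
dropped at load), chained multiple imputation of missing confounders,
and — per imputed dataset — cross-validated learner selection for the
outcome and exposure regressions, the requested estimators
(g-computation, stabilized IPTW, TMLE), and a bootstrap; per-estimator
results are pooled across imputations with Rubin's rules.  The whole
sequence is repeated on the sensitivity-restricted cohort (at least
``min_months`` of observation; recorded users retained only when they
reported COC use at more than ``min_frac`` of visits).  Outputs are a
results table (rows = estimator × analysis), a positivity report, and a
run log; every random stage derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .cohort import CohortSchemaError, read_cohort, write_cohort
from .estimators import (
    DEFAULT_G_BOUNDS,
    LearnerLibrary,
    discrete_super_learner,
    fit_learner,
    g_compute,
    iptw_estimate,
    stabilized_weights,
    tmle_estimate,
)
from .imputation import ImputationConfig, chained_impute, rubins_rule
from .inference import bootstrap, pool_pipeline, positivity_report
from .synthetic_data import ScmParams, load_params, simulate_observed_cohort

__all__ = [
    "AnalysisConfig",
    "CrudeSummary",
    "crude_summary",
    "apply_sensitivity_filter",
    "run_analysis",
]

ESTIMATOR_NAMES = ("gcomp", "iptw", "tmle")


@dataclass
class CrudeSummary:
    """Unadjusted cohort description: counts and crude prevalences."""

    n_total: int
    n_cases: int
    n_exposed: int
    cases_exposed: int
    cases_unexposed: int
    prevalence_exposed: float
    prevalence_unexposed: float
    prevalence_overall: float


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a run from one file.

    ``input`` is either a cohort CSV path or an SCM parameter config
    path (the cohort is then simulated); exactly one must be given.
    """

    input_cohort: str | None = None
    input_params: str | None = None
    estimators: tuple = ESTIMATOR_NAMES
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    learners: LearnerLibrary = field(default_factory=LearnerLibrary)
    B: int = 200
    seed: int = 0
    g_bounds: tuple = DEFAULT_G_BOUNDS
    min_months: float = 6.0
    min_frac: float = 0.2
    max_age: int = 50
    strata_cols: tuple = ("education", "marital", "gravidity")
    logistic_or: bool = True
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.input_cohort is None) == (self.input_params is None):
            raise ValueError("exactly one of input_cohort / input_params must be set")
        if not self.estimators:
            raise ValueError("at least one estimator must be requested")
        unknown = set(self.estimators) - set(ESTIMATOR_NAMES)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        if self.min_months < 0 or not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_months must be >= 0 and min_frac in [0, 1]")
        self.imputation.validate()
        self.learners.validate()

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        imp = ImputationConfig(**doc.pop("imputation", {}))
        learner_doc = doc.pop("learners", {})
        if "learners" in learner_doc:
            learner_doc["learners"] = tuple(learner_doc["learners"])
        lib = LearnerLibrary(**learner_doc)
        for key in ("estimators", "g_bounds", "strata_cols"):
            if key in doc:
                doc[key] = tuple(doc[key])
        cfg = cls(imputation=imp, learners=lib, **doc)
        cfg.validate()
        return cfg


def crude_summary(table: pd.DataFrame) -> CrudeSummary:
    """Exact counts and crude prevalences (on the 0–1 scale); an empty
    table yields zero counts and NaN prevalences."""
    n = len(table)
    if n == 0:
        return CrudeSummary(0, 0, 0, 0, 0, float("nan"), float("nan"), float("nan"))
    a = table["A"].to_numpy(int)
    y = table["Y"].to_numpy(int)
    n_exposed = int(a.sum())
    cases_exposed = int(y[a == 1].sum())
    cases_unexposed = int(y[a == 0].sum())
    return CrudeSummary(
        n_total=n,
        n_cases=int(y.sum()),
        n_exposed=n_exposed,
        cases_exposed=cases_exposed,
        cases_unexposed=cases_unexposed,
        prevalence_exposed=cases_exposed / n_exposed if n_exposed else float("nan"),
        prevalence_unexposed=(cases_unexposed / (n - n_exposed)
                              if n > n_exposed else float("nan")),
        prevalence_overall=int(y.sum()) / n,
    )


def apply_sensitivity_filter(table: pd.DataFrame, min_months: float = 6.0,
                             min_frac: float = 0.2) -> pd.DataFrame:
    """Restrict to records with at least ``min_months`` of observation,
    keeping never-reporters (frac = 0) and records whose reported-use
    fraction exceeds ``min_frac``; records with 0 < frac ≤ min_frac are
    dropped as unreliably classified."""
    for col in ("months_observed", "frac_visits_coc"):
        if col not in table.columns:
            raise CohortSchemaError(f"sensitivity filter requires column {col!r}")
    frac = table["frac_visits_coc"]
    keep = (table["months_observed"] >= min_months) & ((frac == 0) | (frac > min_frac))
    return table.loc[keep].reset_index(drop=True)


def _pooled_logistic_or(tables: list) -> dict:
    """Supplementary conditional odds ratio: main-effects logistic per
    imputed dataset, log-OR pooled by Rubin's rules, exponentiated."""
    logors, variances = [], []
    for t in tables:
        x = sm.add_constant(np.column_stack([
            t["A"].to_numpy(float),
            (t["age"].to_numpy(float) - 34.0) / 8.0,
            t["education"].to_numpy(float),
            t["marital"].to_numpy(float),
            t["gravidity"].to_numpy(float),
            np.log(t["cd4_nadir"].to_numpy(float)) - 5.5,
        ]))
        res = sm.GLM(t["Y"].to_numpy(int), x, family=sm.families.Binomial()).fit()
        logors.append(res.params[1])
        variances.append(res.cov_params()[1, 1])
    pooled = rubins_rule(logors, variances)
    return {"estimate": float(np.exp(pooled.estimate)),
            "ci_low": float(np.exp(pooled.ci_low)),
            "ci_high": float(np.exp(pooled.ci_high))}


def _analyze_cohort(table: pd.DataFrame, cfg: AnalysisConfig, label: str,
                    log: dict) -> tuple:
    """Impute, estimate, bootstrap, and pool one cohort (main or
    sensitivity).  Returns (result rows, positivity report)."""
    imp_cfg = dataclasses.replace(cfg.imputation, seed=cfg.seed + cfg.imputation.seed)
    tables = chained_impute(table, imp_cfg)
    per_est: dict = {name: [] for name in cfg.estimators}
    log[label] = {"n": len(table), "learner_selections": [],
                  "bootstrap_failures": 0}
    g_fit_first = None
    for k, imputed in enumerate(tables):
        sub_seed = cfg.seed + 1000 * (k + 1)
        q_fit = discrete_super_learner(imputed, "outcome", cfg.learners, sub_seed)
        g_fit = discrete_super_learner(imputed, "exposure", cfg.learners, sub_seed)
        g_fit.truncation_bounds = cfg.g_bounds
        if g_fit_first is None:
            g_fit_first = g_fit
        log[label]["learner_selections"].append(
            {"outcome": q_fit.learner_id, "exposure": g_fit.learner_id})

        def run_one(t: pd.DataFrame, name: str, qlid=q_fit.learner_id, glid=g_fit.learner_id):
            # refit the selected learners on the (re)sampled table
            if name == "gcomp":
                return g_compute(t, fit_learner(t, "outcome", qlid))
            g = fit_learner(t, "exposure", glid)
            g.truncation_bounds = cfg.g_bounds
            if name == "iptw":
                return iptw_estimate(t, stabilized_weights(t, g))
            return tmle_estimate(t, fit_learner(t, "outcome", qlid), g)

        for name in cfg.estimators:
            point = run_one(imputed, name)
            boot = bootstrap(imputed, lambda t, n=name: run_one(t, n),
                             B=cfg.B, seed=sub_seed)
            log[label]["bootstrap_failures"] += boot.n_failed
            variance = point.variance if name == "tmle" else boot.boot_se ** 2
            per_est[name].append((point, boot, variance))

    rows = []
    reports = {}
    for name in cfg.estimators:
        triples = per_est[name]
        pooled = pool_pipeline([(p.psi, v) for p, _, v in triples])
        boot_pooled = rubins_rule([b.boot_mean for _, b, _ in triples],
                                  [b.boot_se ** 2 for _, b, _ in triples])
        rows.append({
            "analysis": label, "estimator": name,
            "estimate": pooled.estimate, "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high, "boot_mean": boot_pooled.estimate,
            "boot_ci_low": boot_pooled.ci_low, "boot_ci_high": boot_pooled.ci_high,
        })
        reports[name] = (triples[0][0], triples[0][1])
    if cfg.logistic_or:
        or_row = _pooled_logistic_or(tables)
        rows.append({"analysis": label, "estimator": "logistic_or",
                     "estimate": or_row["estimate"], "ci_low": or_row["ci_low"],
                     "ci_high": or_row["ci_high"], "boot_mean": np.nan,
                     "boot_ci_low": np.nan, "boot_ci_high": np.nan})
    first_name = cfg.estimators[0]
    report = positivity_report(tables[0], g_fit_first,
                               reports[first_name][1], reports[first_name][0],
                               cfg.strata_cols)
    return rows, report


def _load_input(cfg: AnalysisConfig) -> pd.DataFrame:
    if cfg.input_params is not None:
        params = (cfg.input_params if isinstance(cfg.input_params, ScmParams)
                  else load_params(cfg.input_params))
        table = simulate_observed_cohort(params)
    else:
        table = read_cohort(cfg.input_cohort)
    return table.loc[table["age"] < cfg.max_age].reset_index(drop=True)


def _write_outputs(out_dir: Path, results: pd.DataFrame, crude: CrudeSummary,
                   reports: dict, log: dict) -> None:
    results.to_csv(out_dir / "results.csv", index=False, float_format="%.3f")
    with open(out_dir / "positivity.txt", "w") as fh:
        for label, rep in reports.items():
            fh.write(f"== positivity: {label} analysis ==\n")
            fh.write(f"strata examined: {rep.n_strata}; "
                     f"flagged (an arm empty): {len(rep.flagged_strata)}\n")
            fh.write(f"raw propensities outside truncation bounds: {rep.g_extremes}\n")
            fh.write(f"bootstrap symmetry: mean-minus-point = {rep.symmetry[0]:.4f}, "
                     f"skewness = {rep.symmetry[1]:.3f}\n")
            for s in rep.flagged_strata:
                fh.write(f"  {s}\n")
    pd.concat([rep.to_frame().assign(analysis=label)
               for label, rep in reports.items()],
              ignore_index=True).to_csv(out_dir / "positivity.csv", index=False)
    log["crude"] = dataclasses.asdict(crude)
    with open(out_dir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the main and sensitivity analyses end-to-end.

    Returns a dict with the results table, the crude summary, the two
    positivity reports, and the run log; the same artifacts are written
    to ``cfg.out_dir`` when set.  Any stage failure removes partial
    outputs and re-raises with the stage named.
    """
    cfg.validate()
    log: dict = {"seed": cfg.seed, "estimators": list(cfg.estimators),
                 "B": cfg.B, "m": cfg.imputation.m}
    stage = "load"
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        table = _load_input(cfg)
        stage = "crude"
        crude = crude_summary(table)
        stage = "main"
        main_rows, main_report = _analyze_cohort(table, cfg, "main", log)
        stage = "sensitivity"
        filtered = apply_sensitivity_filter(table, cfg.min_months, cfg.min_frac)
        sens_rows, sens_report = _analyze_cohort(filtered, cfg, "sensitivity", log)
        results = pd.DataFrame(main_rows + sens_rows)
        reports = {"main": main_report, "sensitivity": sens_report}
        if out_dir is not None:
            stage = "write"
            if cfg.input_cohort is None:
                write_cohort(table, out_dir / "cohort.csv")
            _write_outputs(out_dir, results, crude, reports, log)
    except Exception as exc:
        if out_dir is not None:
            for name in ("results.csv", "positivity.txt", "positivity.csv",
                         "run_log.yaml", "cohort.csv"):
                (out_dir / name).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed during {stage!r} stage: {exc}") from exc
    return {"results": results, "crude": crude, "reports": reports, "log": log}
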