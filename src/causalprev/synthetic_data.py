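"""Cohort simulation from a known structural causal model.

The generator encodes the reduced confounder → exposure → outcome graph
(W → A → Y) as a structural causal model with logistic links:

.. math::

    A \\sim \\mathrm{Bernoulli}(\\mathrm{expit}(\\beta_A^\\top x(W))), \\qquad
    Y \\sim \\mathrm{Bernoulli}(\\mathrm{expit}(\\beta_Y^\\top x(W, A))),

where :math:`W` collects five baseline confounders (age, education,
marital status, gravidity, CD4+ nadir) drawn from independent stylized
marginals.  The exposure coefficient in ``beta_Y`` is the causal knob: it
determines the true marginal prevalence difference

.. math::

    \\psi = E[Y(1)] - E[Y(0)],

which :func:`true_prevalence_difference` computes either by exact
enumeration over discrete confounder strata or by Monte Carlo averaging
of :math:`\\mathrm{expit}(\\beta_Y^\\top x(W,1)) -
\\mathrm{expit}(\\beta_Y^\\top x(W,0))`.

On top of the clean cohort two observation processes can be layered:
missing-at-random deletion of confounder cells driven by always-observed
columns (:func:`apply_mar_missingness`) and misclassification of the
recorded exposure with configurable sensitivity and specificity
(:func:`misclassify_exposure`).  All stages derive independent random
substreams from one integer seed, so identical parameters reproduce
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import poisson

from .cohort import MISSABLE, validate_cohort

__all__ = [
    "ConfounderSpec",
    "VisitSpec",
    "ScmParams",
    "ScmParamsError",
    "generate_cohort",
    "true_prevalence_difference",
    "apply_mar_missingness",
    "misclassify_exposure",
    "simulate_observed_cohort",
    "load_params",
    "save_params",
]

# centering/scaling constants for linear-predictor terms
AGE_CENTER = 34.0
AGE_SCALE = 8.0
LOG_CD4_CENTER = 5.5

#: linear-predictor terms derived from discrete confounders (enumerable)
_DISCRETE_TERMS = {"age_std", "age_std_sq", "education", "marital", "gravidity"}
_ALL_TERMS = {"intercept", "A"} | _DISCRETE_TERMS | {"log_cd4_c"}

#: columns miss_spec logits may condition on (always observed)
_MAR_PREDICTORS = {"intercept", "A", "Y", "age", "age_std"}

# substream labels → spawn keys off the global seed
_STREAMS = {"confounders": 0, "exposure": 1, "outcome": 2, "visits": 3,
            "missingness": 4, "misclassification": 5}


class ScmParamsError(ValueError):
    """Invalid structural-causal-model parameterization (names the field)."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class ConfounderSpec:
    """Marginal distributions of the five baseline confounders.

    Age is uniform on an integer range (years); education is categorical
    over 4 ordered levels; marital status is Bernoulli; gravidity is a
    Poisson count truncated to ``[0, gravidity_max]``; CD4+ nadir
    (cells/µL) is log-normal.
    """

    age_min: int = 18
    age_max: int = 49
    education_probs: tuple = (0.15, 0.45, 0.30, 0.10)
    marital_p: float = 0.6
    gravidity_lambda: float = 3.0
    gravidity_max: int = 12
    cd4_log_mean: float = 5.5
    cd4_log_sd: float = 0.8

    def validate(self) -> None:
        if not self.age_min <= self.age_max:
            raise ScmParamsError("confounder_spec.age_min must be <= age_max")
        p = np.asarray(self.education_probs, dtype=float)
        if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ScmParamsError("confounder_spec.education_probs must be a proper distribution")
        if not 0.0 <= self.marital_p <= 1.0:
            raise ScmParamsError("confounder_spec.marital_p must lie in [0, 1]")
        if self.gravidity_lambda <= 0 or self.gravidity_max < 0:
            raise ScmParamsError("confounder_spec.gravidity_lambda must be positive")
        if self.cd4_log_sd <= 0:
            raise ScmParamsError("confounder_spec.cd4_log_sd must be positive")


@dataclass
class VisitSpec:
    """Observation metadata: months observed (gamma) and, for recorded
    COC users, the fraction of visits reporting COC (beta on (0, 1])."""

    months_shape: float = 2.0
    months_mean: float = 24.0
    frac_alpha: float = 2.0
    frac_beta: float = 2.0
    # spurious reporters (recorded users who never truly used COC) report
    # at few visits; their fraction is drawn from a low-mass beta
    fp_frac_alpha: float = 1.0
    fp_frac_beta: float = 6.0

    def validate(self) -> None:
        if self.months_shape <= 0 or self.months_mean <= 0:
            raise ScmParamsError("visit_spec months parameters must be positive")
        if min(self.frac_alpha, self.frac_beta,
               self.fp_frac_alpha, self.fp_frac_beta) <= 0:
            raise ScmParamsError("visit_spec frac beta parameters must be positive")


@dataclass
class ScmParams:
    """Full parameterization of the data-generating process.

    ``beta_A`` and ``beta_Y`` map linear-predictor term names to
    coefficients.  Recognised terms: ``intercept``, ``age_std``
    ((age − 34)/8), ``age_std_sq``, ``education`` (ordinal 0–3),
    ``marital``, ``gravidity``, ``log_cd4_c`` (log CD4 nadir − 5.5) and,
    in ``beta_Y`` only, ``A`` — the causal exposure coefficient.

    ``miss_spec`` maps a missable confounder column to a logit
    specification over always-observed predictors (``intercept``, ``A``,
    ``Y``, ``age``, ``age_std``); each cell of that column is deleted
    independently with probability expit(logit).  ``misclass`` is the
    (sensitivity, specificity) of the recorded exposure relative to the
    true exposure; (1, 1) records exposure faithfully.
    """

    n: int = 2519
    beta_A: dict = field(default_factory=dict)
    beta_Y: dict = field(default_factory=dict)
    confounder_spec: ConfounderSpec = field(default_factory=ConfounderSpec)
    visit_spec: VisitSpec = field(default_factory=VisitSpec)
    miss_spec: dict = field(default_factory=dict)
    misclass: tuple = (1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ScmParamsError("n must be >= 1")
        self.confounder_spec.validate()
        self.visit_spec.validate()
        for name, beta in (("beta_A", self.beta_A), ("beta_Y", self.beta_Y)):
            unknown = set(beta) - _ALL_TERMS
            if unknown:
                raise ScmParamsError(f"{name} references unknown terms: {sorted(unknown)}")
        if "A" in self.beta_A:
            raise ScmParamsError("beta_A must not reference the exposure term 'A'")
        sens, spec = self.misclass
        if not (0.0 < sens <= 1.0 and 0.0 < spec <= 1.0):
            raise ScmParamsError("misclass sensitivity and specificity must lie in (0, 1]")
        for col, logits in self.miss_spec.items():
            if col not in MISSABLE:
                raise ScmParamsError(f"miss_spec targets non-missable column {col!r}")
            bad = set(logits) - _MAR_PREDICTORS
            if bad:
                raise ScmParamsError(
                    f"miss_spec for {col!r} conditions on non-always-observed "
                    f"predictors {sorted(bad)} (would violate MAR-by-construction)")


def _terms_frame(table: pd.DataFrame, a: np.ndarray | int | None = None) -> dict:
    """Evaluate every linear-predictor term on a cohort table."""
    out = {
        "intercept": np.ones(len(table)),
        "age_std": (table["age"].to_numpy(float) - AGE_CENTER) / AGE_SCALE,
        "education": table["education"].to_numpy(float),
        "marital": table["marital"].to_numpy(float),
        "gravidity": table["gravidity"].to_numpy(float),
    }
    out["age_std_sq"] = out["age_std"] ** 2
    if "cd4_nadir" in table.columns:
        cd4 = table["cd4_nadir"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            out["log_cd4_c"] = np.log(cd4) - LOG_CD4_CENTER
    if a is not None:
        out["A"] = np.broadcast_to(np.asarray(a, dtype=float), (len(table),))
    return out


def linear_predictor(beta: dict, table: pd.DataFrame,
                     a: np.ndarray | int | None = None) -> np.ndarray:
    """beta·x evaluated row-wise on a cohort table (optionally forcing A)."""
    terms = _terms_frame(table, a)
    lp = np.zeros(len(table))
    for name, coef in beta.items():
        lp += coef * terms[name]
    return lp


def _draw_confounders(spec: ConfounderSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    education = rng.choice(len(spec.education_probs), size=n, p=np.asarray(spec.education_probs))
    marital = rng.binomial(1, spec.marital_p, size=n)
    # truncated Poisson via renormalized pmf on [0, gravidity_max]
    ks = np.arange(spec.gravidity_max + 1)
    pmf = poisson.pmf(ks, spec.gravidity_lambda)
    pmf = pmf / pmf.sum()
    gravidity = rng.choice(ks, size=n, p=pmf)
    cd4 = np.exp(rng.normal(spec.cd4_log_mean, spec.cd4_log_sd, size=n))
    return pd.DataFrame({
        "age": age, "education": education, "marital": marital,
        "gravidity": gravidity, "cd4_nadir": cd4,
    })


def _draw_frac_visits(a: np.ndarray, spec: VisitSpec, rng: np.random.Generator,
                      true_a: np.ndarray | None = None) -> np.ndarray:
    """Fraction of visits reporting COC: 0 for recorded non-users, a
    Beta(frac_alpha, frac_beta) draw for recorded users; when the latent
    truth is supplied, spurious reporters (recorded 1, truly 0) draw
    from the low-mass Beta(fp_frac_alpha, fp_frac_beta) instead."""
    frac = np.zeros(len(a))
    users = a == 1
    if users.any():
        frac[users] = rng.beta(spec.frac_alpha, spec.frac_beta, size=int(users.sum()))
    if true_a is not None:
        spurious = users & (np.asarray(true_a) == 0)
        if spurious.any():
            frac[spurious] = rng.beta(spec.fp_frac_alpha, spec.fp_frac_beta,
                                      size=int(spurious.sum()))
    return frac


def generate_cohort(params: ScmParams) -> pd.DataFrame:
    """Draw a clean cohort from the structural causal model.

    Returns ``params.n`` records with confounders, exposure ``A``
    (faithfully recorded, duplicated in ``true_A``), outcome ``Y``, and
    observation metadata.  No missingness or misclassification is applied
    at this stage.  Deterministic given ``params.seed``.
    """
    params.validate()
    w = _draw_confounders(params.confounder_spec, params.n, _rng(params.seed, "confounders"))
    p_a = expit(linear_predictor(params.beta_A, w))
    a = _rng(params.seed, "exposure").binomial(1, p_a)
    p_y = expit(linear_predictor(params.beta_Y, w, a))
    y = _rng(params.seed, "outcome").binomial(1, p_y)
    visit_rng = _rng(params.seed, "visits")
    months = visit_rng.gamma(params.visit_spec.months_shape,
                             params.visit_spec.months_mean / params.visit_spec.months_shape,
                             size=params.n)
    frac = _draw_frac_visits(a, params.visit_spec, visit_rng)
    table = w.assign(A=a, Y=y, months_observed=months, frac_visits_coc=frac, true_A=a)
    validate_cohort(table, require_metadata=True)
    return table


def _enumerable(beta_Y: dict) -> bool:
    return set(beta_Y) - {"intercept", "A"} <= _DISCRETE_TERMS


def true_prevalence_difference(params: ScmParams, n_mc: int = 200_000) -> float:
    """True ψ = E[Y(1)] − E[Y(0)] implied by the SCM.

    When the outcome model involves only discrete confounder terms the
    expectation is computed exactly by enumerating confounder strata
    weighted by their probabilities; otherwise by Monte Carlo with
    ``n_mc`` confounder draws (seeded off ``params.seed``).
    """
    params.validate()
    if n_mc < 1:
        raise ScmParamsError("n_mc must be >= 1")
    beta = params.beta_Y
    b_a = beta.get("A", 0.0)
    spec = params.confounder_spec
    if _enumerable(beta):
        used = set(beta) - {"intercept", "A"}
        axes, weights = [], []
        # enumerate only variables the outcome model actually uses
        if used & {"age_std", "age_std_sq"}:
            ages = np.arange(spec.age_min, spec.age_max + 1)
            axes.append(("age", ages))
            weights.append(np.full(len(ages), 1.0 / len(ages)))
        if "education" in used:
            axes.append(("education", np.arange(len(spec.education_probs))))
            weights.append(np.asarray(spec.education_probs, dtype=float))
        if "marital" in used:
            axes.append(("marital", np.array([0, 1])))
            weights.append(np.array([1 - spec.marital_p, spec.marital_p]))
        if "gravidity" in used:
            ks = np.arange(spec.gravidity_max + 1)
            pmf = poisson.pmf(ks, spec.gravidity_lambda)
            axes.append(("gravidity", ks))
            weights.append(pmf / pmf.sum())
        if not axes:  # intercept-only: closed form
            c = beta.get("intercept", 0.0)
            return float(expit(c + b_a) - expit(c))
        names = [name for name, _ in axes]
        grid = pd.DataFrame(list(itertools.product(*(vals for _, vals in axes))), columns=names)
        for col in ("age", "education", "marital", "gravidity"):
            if col not in grid.columns:
                grid[col] = 0
        prob = np.ones(len(grid))
        for (name, vals), w in zip(axes, weights):
            idx = pd.Index(vals).get_indexer(grid[name])
            prob *= w[idx]
        diff = expit(linear_predictor(beta, grid, 1)) - expit(linear_predictor(beta, grid, 0))
        return float(np.sum(prob * diff))
    w = _draw_confounders(spec, n_mc, _rng(params.seed, "confounders"))
    diff = expit(linear_predictor(beta, w, 1)) - expit(linear_predictor(beta, w, 0))
    return float(diff.mean())


def apply_mar_missingness(table: pd.DataFrame, params: ScmParams) -> pd.DataFrame:
    """Delete confounder cells missing-at-random per ``params.miss_spec``.

    Each targeted cell is set to NA independently with probability
    expit of a logit built from always-observed columns only, so the
    mechanism is MAR by construction.  ``A`` and ``Y`` are never touched
    and the record count is unchanged.
    """
    params.validate()
    out = table.copy()
    rng = _rng(params.seed, "missingness")
    always = {
        "intercept": np.ones(len(out)),
        "A": out["A"].to_numpy(float),
        "Y": out["Y"].to_numpy(float),
        "age": out["age"].to_numpy(float),
        "age_std": (out["age"].to_numpy(float) - AGE_CENTER) / AGE_SCALE,
    }
    for col in MISSABLE:  # fixed iteration order keeps the stream reproducible
        if col not in params.miss_spec:
            continue
        logit = np.zeros(len(out))
        for name, coef in params.miss_spec[col].items():
            logit += coef * always[name]
        drop = rng.random(len(out)) < expit(logit)
        if drop.any():
            out[col] = out[col].astype(float)
            out.loc[drop, col] = np.nan
    return out


def misclassify_exposure(table: pd.DataFrame, sensitivity: float, specificity: float,
                         seed: int, visit_spec: VisitSpec | None = None) -> pd.DataFrame:
    """Record exposure with error relative to the latent ``true_A``.

    True users are recorded exposed with probability ``sensitivity``,
    true non-users recorded unexposed with probability ``specificity``;
    ``frac_visits_coc`` is regenerated to stay consistent with the
    recorded value (positive beta draw for recorded users, 0 otherwise),
    with spurious reporters drawing from the low-mass false-positive
    beta so that a visit-fraction threshold preferentially removes them.
    """
    if "true_A" not in table.columns:
        raise ValueError("misclassify_exposure requires the latent 'true_A' column")
    if not (0.0 < sensitivity <= 1.0 and 0.0 < specificity <= 1.0):
        raise ScmParamsError("sensitivity and specificity must lie in (0, 1]")
    visit_spec = visit_spec or VisitSpec()
    out = table.copy()
    rng = _rng(seed, "misclassification")
    true_a = out["true_A"].to_numpy(int)
    u = rng.random(len(out))
    recorded = np.where(true_a == 1, (u < sensitivity).astype(int), (u >= specificity).astype(int))
    out["A"] = recorded
    out["frac_visits_coc"] = _draw_frac_visits(recorded, visit_spec, rng, true_a)
    return out


def simulate_observed_cohort(params: ScmParams) -> pd.DataFrame:
    """Generate a cohort and apply the observation layers in order:
    exposure misclassification (if configured), then MAR missingness."""
    table = generate_cohort(params)
    sens, spec = params.misclass
    if (sens, spec) != (1.0, 1.0):
        table = misclassify_exposure(table, sens, spec, params.seed, params.visit_spec)
    if params.miss_spec:
        table = apply_mar_missingness(table, params)
    return table


# ---------------------------------------------------------------------------
# config serialization

def save_params(params: ScmParams, path) -> None:
    """Serialize parameters to a nested key-value (YAML) config file."""
    doc = {
        "n": params.n,
        "seed": params.seed,
        "beta_A": dict(params.beta_A),
        "beta_Y": dict(params.beta_Y),
        "confounder_spec": dataclasses.asdict(params.confounder_spec),
        "visit_spec": dataclasses.asdict(params.visit_spec),
        "miss_spec": {k: dict(v) for k, v in params.miss_spec.items()},
        "misclass": {"sensitivity": params.misclass[0], "specificity": params.misclass[1]},
    }
    doc["confounder_spec"]["education_probs"] = list(params.confounder_spec.education_probs)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> ScmParams:
    """Load :class:`ScmParams` from a config file written by :func:`save_params`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cs = doc.get("confounder_spec", {})
    if "education_probs" in cs:
        cs["education_probs"] = tuple(cs["education_probs"])
    mc = doc.get("misclass", {"sensitivity": 1.0, "specificity": 1.0})
    params = ScmParams(
        n=doc["n"],
        beta_A=doc.get("beta_A", {}),
        beta_Y=doc.get("beta_Y", {}),
        confounder_spec=ConfounderSpec(**cs),
        visit_spec=VisitSpec(**doc.get("visit_spec", {})),
        miss_spec=doc.get("miss_spec", {}) or {},
        misclass=(mc["sensitivity"], mc["specificity"]),
        seed=doc.get("seed", 0),
    )
    params.validate()
    return params
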