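"""Cohort table schema and delimited-text I/O.

A cohort is a :class:`pandas.DataFrame`, one row per woman, with fixed
column names:

========================  =============================================
column                    meaning
========================  =============================================
``age``                   age in years (integer, always observed)
``education``             ordinal educational attainment 0–3
                          (none, primary, secondary, post-secondary)
``marital``               married / cohabiting indicator {0, 1}
``gravidity``             number of pregnancies (0–12)
``cd4_nadir``             lowest recorded CD4+ count, cells/µL
``A``                     recorded combined-oral-contraceptive ever-use
``Y``                     CIN2+ diagnosis at screening {0, 1}
``months_observed``       months of clinic observation before screening
``frac_visits_coc``       fraction of visits at which COC use was
                          reported; 0 exactly for recorded non-users
``true_A``                latent true exposure (simulation output only)
========================  =============================================

Missing values are permitted only in the confounder columns; ``A`` and
``Y`` are always complete.  On disk a cohort is a comma-separated file
with a header row and empty fields for missing values.
"""

from __future__ import annotations

import pandas as pd

#: confounder columns, in canonical order
CONFOUNDERS = ["age", "education", "marital", "gravidity", "cd4_nadir"]

#: columns that may contain missing values
MISSABLE = ["education", "marital", "gravidity", "cd4_nadir"]

#: observation-metadata columns
METADATA = ["months_observed", "frac_visits_coc"]

#: full canonical column order (``true_A`` is optional and kept last)
COLUMNS = CONFOUNDERS + ["A", "Y"] + METADATA


class CohortSchemaError(ValueError):
    """Raised when a table does not conform to the cohort schema."""


def validate_cohort(table: pd.DataFrame, require_metadata: bool = False) -> None:
    """Check schema invariants, raising :class:`CohortSchemaError` on failure.

    Verifies column presence, completeness of ``A`` and ``Y``, their binary
    coding, and the ``frac_visits_coc`` consistency rule (zero for recorded
    non-users, within [0, 1] otherwise).
    """
    required = CONFOUNDERS + ["A", "Y"]
    if require_metadata:
        required = required + METADATA
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise CohortSchemaError(f"missing required columns: {missing_cols}")
    for col in ("A", "Y"):
        s = table[col]
        if s.isna().any():
            raise CohortSchemaError(f"column {col!r} must not contain missing values")
        if not s.isin([0, 1]).all():
            raise CohortSchemaError(f"column {col!r} must be binary 0/1")
    if "frac_visits_coc" in table.columns:
        frac = table["frac_visits_coc"]
        if ((frac < 0) | (frac > 1)).any():
            raise CohortSchemaError("frac_visits_coc must lie in [0, 1]")
        if ((table["A"] == 0) & (frac != 0)).any():
            raise CohortSchemaError("frac_visits_coc must be 0 for recorded non-users")
    if "months_observed" in table.columns and (table["months_observed"] < 0).any():
        raise CohortSchemaError("months_observed must be non-negative")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort as comma-separated text (empty field = missing)."""
    table.to_csv(path, index=False)


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort`."""
    table = pd.read_csv(path)
    if validate:
        validate_cohort(table)
    return table
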