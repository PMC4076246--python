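import copy
from importlib.resources import files

import numpy as np
import pytest

from causalprev.causal_dag import read_dag
from causalprev.synthetic_data import generate_cohort, load_params

FIXTURES = files("causalprev") / "fixtures"


@pytest.fixture()
def kisumu_params():
    """Fresh copy of the shipped cohort-emulation parameters."""
    return load_params(FIXTURES / "kisumu_like.cfg")


@pytest.fixture()
def confounded_params():
    """Fresh copy of the strongly confounded fixture parameters."""
    return load_params(FIXTURES / "confounded.cfg")


@pytest.fixture(scope="session")
def _kisumu_clean_cohort():
    params = load_params(FIXTURES / "kisumu_like.cfg")
    params.miss_spec = {}
    return generate_cohort(params)


@pytest.fixture()
def kisumu_cohort(_kisumu_clean_cohort):
    """n=2519 complete cohort from the shipped fixture (no missingness)."""
    return _kisumu_clean_cohort.copy()


@pytest.fixture(scope="session")
def panel_a():
    return read_dag(FIXTURES / "dags/panel_a.txt")


@pytest.fixture(scope="session")
def panel_b():
    return read_dag(FIXTURES / "dags/panel_b.txt")


@pytest.fixture(scope="session")
def panel_c():
    return read_dag(FIXTURES / "dags/panel_c.txt")


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
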