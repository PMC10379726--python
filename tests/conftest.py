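import numpy as np
import pytest

from fctpath.synthetic import CohortConfig, generate_cohort
from fctpath.tables import read_newick

TOY_NEWICK = "((A:1,B:2):0.5,C:3);"


@pytest.fixture(scope="session")
def toy_tree():
    return read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def small_cohort():
    """24 infants, no dropout: 96 samples. Fast enough for most stages."""
    cfg = CohortConfig(n_infants=24, dropout_prob=0.0)
    return generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-scale cohort (~130 infants, ~480-500 samples)."""
    return generate_cohort(seed=1)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: results never depend on
    test execution order."""
    return np.random.default_rng(2024)
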