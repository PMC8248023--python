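import numpy as np
import pytest

from longiconn.build import build_cohort_pair
from longiconn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_null_cohort():
    """A small null cohort (no planted effect) shared across tests."""
    cfg = CohortConfig(n_subjects=8, n_nodes=20, base_density=0.5, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_null_pair(small_null_cohort):
    pair, mask = build_cohort_pair(small_null_cohort.counts,
                                   small_null_cohort.waytotals)
    return pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
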