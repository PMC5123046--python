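import numpy as np
import pytest

from consensusref import PopulationModel, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by fast unit tests."""
    model = PopulationModel(ref_length=8_000, n_snv_sites=120, n_indel_sites=30)
    return simulate_cohort(model, seed=42)


@pytest.fixture(scope="session")
def default_cohort():
    """The headline study-condition cohort (50 kb, 2,000 + 200 sites, n=40)."""
    return simulate_cohort(PopulationModel(), seed=1)
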