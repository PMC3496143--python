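import numpy as np
import pytest
from hypothesis import settings

from mammorisk import effects as eff
from mammorisk import synthetic as syn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return eff.load_reference_effects()


@pytest.fixture(scope="session")
def ref():
    return eff.ReferenceDistribution.default()


@pytest.fixture(scope="session")
def schedule():
    return syn.generate_hazard_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded case-control cohort shared across tests."""
    cfg = syn.GeneratorConfig(n_cases=1500, n_controls=1500)
    return syn.generate_cohort(cfg, seed=2012)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120207)
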