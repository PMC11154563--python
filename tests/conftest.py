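import numpy as np
import pytest

from ppghb.synth import SimConfig, default_extinction_table, simulate, simulate_cohort


@pytest.fixture(scope="session")
def ext_table():
    return default_extinction_table()


@pytest.fixture(scope="session")
def clean_record(ext_table):
    """Noise-free default record with its ground truth."""
    return simulate(SimConfig(seed=1), ext_table)


@pytest.fixture(scope="session")
def small_cohort(ext_table):
    """A 12-record mixed-quality cohort shared across tests."""
    return simulate_cohort(12, quality_mix=0.25, seed=3, ext=ext_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
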