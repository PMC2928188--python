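import logging

import numpy as np
import pytest

from mscan.synthetic_data import SimConfig, make_study_fixture, simulate_island_neutral

logging.getLogger("mscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_fixture():
    """The deterministic 10-population, 51-locus study-shaped dataset."""
    return make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def neutral_small():
    """A small neutral island-model dataset for estimator tests."""
    cfg = SimConfig(n_demes=16, sampled_pops=6, sample_sizes=[30] * 6,
                    n_loci=30, mutation_model="IAM", theta=0.08,
                    migration_rate=0.002, deme_size=1000.0, seed=11)
    return simulate_island_neutral(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
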