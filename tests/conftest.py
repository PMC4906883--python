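import numpy as np
import pytest

from perturbfatigue import synthetic as syn


@pytest.fixture(scope="session")
def tiny_config():
    """Scaled-down study conditions: 2 sets of 8 trials, light noise."""
    cfg = syn.paper_preset()
    cfg.min_sets = 2
    cfg.max_sets = 2
    cfg.n_subjects = 2
    return cfg


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return syn.generate_cohort(tiny_config, seed=11)


@pytest.fixture(scope="session")
def tiny_session(tiny_cohort):
    return tiny_cohort[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
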