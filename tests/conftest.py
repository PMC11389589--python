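import numpy as np
import pytest
from hypothesis import settings

from vmrloc.config import SimParams, experiment_config
from vmrloc.simulate import simulate_experiment

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def exp1_small():
    """Small reaiming-experiment dataset (pointer, 2 subjects, 2 blocks)."""
    cfg = experiment_config("exp1", "pointer", n_blocks=2, baseline_block=False)
    return simulate_experiment(cfg, SimParams(seed=11), n_subjects=2, seed=11)


@pytest.fixture(scope="session")
def exp1_afc_small():
    cfg = experiment_config("exp1", "afc2")   # 7 blocks
    return simulate_experiment(cfg, SimParams(seed=5), n_subjects=6, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
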