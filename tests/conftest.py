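import numpy as np
import pytest

from warfdose import cohortsim
from warfdose.dataset import make_split
from warfdose.models import DoseModelConfig
from warfdose.train import resolve_fold, train_one


@pytest.fixture(scope="session")
def tiny_cohort():
    """24 simulated patients; shared read-only across tests."""
    return cohortsim.simulate_cohort(24, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """120 simulated patients for split/evaluation tests."""
    return cohortsim.simulate_cohort(120, seed=23)


@pytest.fixture(scope="session")
def small_config():
    return DoseModelConfig(hidden_size=8, num_layers=1, ffn_hidden=8,
                           learning_rate=0.01, seed=5)


@pytest.fixture(scope="session")
def dose_results(small_cohort, small_config):
    """A quickly trained dose model used by prediction/evaluation tests."""
    split = make_split(small_cohort, seed=23)
    fold = resolve_fold(small_cohort, split)
    return train_one(small_config, fold, max_epochs=6)


@pytest.fixture(scope="session")
def dose_artifact(dose_results):
    return dose_results.artifact
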