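import numpy as np
import pytest

from loomsync.synthetic import SimConfig, simulate_experiment, triples_from_truth
from loomsync.trajectory_io import build_velocity_matrix


@pytest.fixture(scope="session")
def small_experiment():
    """A 3-group x 4-trial simulated experiment (tables + ground truth)."""
    cfg = SimConfig(n_groups=3, n_trials=4, seed=11)
    tables, truth = simulate_experiment(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_vm(small_experiment):
    _, tables, _ = small_experiment
    return build_velocity_matrix(tables)


@pytest.fixture(scope="session")
def familiar_truth():
    """Ground-truth states for a full familiar design (17 groups x 10 trials)."""
    from loomsync.synthetic import simulate_states

    return simulate_states(SimConfig(seed=7))


@pytest.fixture(scope="session")
def familiar_triples(familiar_truth):
    return triples_from_truth(familiar_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
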