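import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import utag.quant as quant
import utag.stats as stats
import utag.synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    """Reference synthetic experiment: 2000 genes, 200 targets, f=0.2,
    tails uniform 4-13, e=0.05, one million reads, seed 1."""
    return syn.SimulationParams(seed=1)


@pytest.fixture(scope="session")
def default_truth(default_params):
    return syn.simulate_truth(default_params)


@pytest.fixture(scope="session")
def active_matrix(default_truth, default_params):
    return syn.simulate_ucount_matrix(default_truth, default_params)


@pytest.fixture(scope="session")
def dead_matrix(default_truth, default_params):
    return syn.simulate_dead_control(default_truth, default_params)


@pytest.fixture(scope="session")
def active_profile(active_matrix):
    return stats.compute_profile(quant.normalize_rpm(active_matrix))


@pytest.fixture(scope="session")
def true_target_ids(default_truth):
    return set(np.array(default_truth.gene_ids)[default_truth.target_flags])
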