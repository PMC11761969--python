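import numpy as np
import pytest

from oceanforage import AgentParams, CohortSpec, TaskConfig, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def cfg_small():
    """Short sessions for fast tests."""
    return TaskConfig(n_blocks=6)


@pytest.fixture(scope="session")
def cohort_small(cfg_small):
    """Five default agents on short sessions, shared across tests."""
    logs, truth = generate_cohort(CohortSpec(n_agents=5, seed=321), cfg_small)
    return logs, truth


@pytest.fixture(scope="session")
def cohort_default(cfg):
    """A full-size default cohort (23 agents x 27 blocks), shared."""
    logs, truth = generate_cohort(CohortSpec(n_agents=23, seed=2024), cfg)
    return logs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(99)
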