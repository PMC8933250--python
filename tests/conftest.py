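import numpy as np
import pytest

from cpmnet import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_planted_cohort():
    """30 subjects, 20 nodes, 4+4 planted edges at effect .6."""
    cfg = SimulationConfig(
        n_subjects=30,
        n_nodes=20,
        n_planted_positive=4,
        n_planted_negative=4,
        effect_size=0.6,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """100 subjects, 40 nodes, 8+7 planted edges at effect .6."""
    cfg = SimulationConfig(
        n_subjects=100,
        n_nodes=40,
        n_planted_positive=8,
        n_planted_negative=7,
        effect_size=0.6,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
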