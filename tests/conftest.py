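import numpy as np
import pytest

from actiwear import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 4 days under default study conditions."""
    return simulate_cohort(SimulationConfig(n_subjects=10, days_per_subject=4, seed=11))


@pytest.fixture(scope="session")
def hard_cohort_small():
    """10 subjects x 4 days with long motionless sedentary bouts."""
    return simulate_cohort(
        SimulationConfig.hard_regime(n_subjects=10, days_per_subject=4, seed=12)
    )
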