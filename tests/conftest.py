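import numpy as np
import pytest

from thymospec.synthetic import CohortConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A reduced cohort (fast) that still supports the 12-HC reference."""
    return CohortConfig(group_sizes={"pHIVy": 4, "npHIVy": 4, "HC": 14}, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
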