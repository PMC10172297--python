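import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sirrank.cohort import CohortSchema, CohortTable
from sirrank.synthetic import CohortGenerator, GeneratorConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

POOL_SEED = 1  # master seed of the shared default synthetic pool


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Three hospitals, nine patients, one covariate; hand-checkable."""
    frame = pd.DataFrame(
        {
            "hospital_id": ["A"] * 3 + ["B"] * 4 + ["C"] * 2,
            "outcome": [1, 0, 0, 1, 1, 0, 0, 0, 1],
            "x1": [0.5, -0.2, 0.1, 1.0, 0.0, -0.5, 0.3, 0.2, -1.0],
        }
    )
    return CohortTable(frame, CohortSchema("hospital_id", "outcome", ("x1",)))


@pytest.fixture(scope="session")
def small_generator() -> CohortGenerator:
    """Quick pool for fit-based unit tests: 40 mid-size hospitals, ~10% rate."""
    cfg = GeneratorConfig(
        m=40,
        volume_min=60,
        volume_max=160,
        volume_mean=100,
        anchor_volumes=(),
        target_rate=0.12,
        sigma_alpha=0.8,
    )
    return CohortGenerator(cfg)


@pytest.fixture(scope="session")
def small_synth(small_generator):
    return small_generator.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def default_generator() -> CohortGenerator:
    return CohortGenerator(GeneratorConfig())


@pytest.fixture(scope="session")
def default_pool(default_generator):
    """The emulated 149-hospital colon-surgery pool (N ~ 39k, rate ~3%)."""
    return default_generator.generate_cohort(seed=POOL_SEED)
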