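import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clix.cohort import score_cohort
from clix.report import analysis_frame
from clix.simulate import SimConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_cohort():
    """A default synthetic cohort (n=2000) with its hidden truth table."""
    records, truth = generate(SimConfig(n_cases=2000, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def scored_frame(sim_cohort):
    """The same cohort scored and merged with covariates."""
    records, truth = sim_cohort
    scored, reference = score_cohort(records)
    frame = analysis_frame(records, scored)
    return frame, truth, reference


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
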