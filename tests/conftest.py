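import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from frailgait import CohortConfig, SubjectProfile, generate_walk_trace


@pytest.fixture(scope="session")
def cohort_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def frail_profile() -> SubjectProfile:
    return SubjectProfile.frail()


@pytest.fixture(scope="session")
def nonfrail_profile() -> SubjectProfile:
    return SubjectProfile.non_frail()


@pytest.fixture(scope="session")
def frail_walk(frail_profile, cohort_config):
    """One seeded frail walk recording with its ground truth."""
    return generate_walk_trace(frail_profile, cohort_config, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
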