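import numpy as np
import pytest
from hypothesis import settings

from asterdrag import (
    baseline_geometry,
    baseline_params,
    run,
    summarize,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: fixed ensemble seeds for the averaged-dynamics fixtures
ENSEMBLE_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def geometry():
    return baseline_geometry()


@pytest.fixture(scope="session")
def params():
    return baseline_params()


@pytest.fixture(scope="session")
def baseline_trajectories(params, geometry):
    """Ten baseline 45-minute runs (the averaged-dynamics ensemble)."""
    return [run(params, geometry, seed=s) for s in ENSEMBLE_SEEDS]


@pytest.fixture(scope="session")
def baseline_summaries(baseline_trajectories):
    return [summarize(t) for t in baseline_trajectories]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
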