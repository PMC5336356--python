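import warnings

import numpy as np
import pytest

from syndromap import (
    CoverConfig,
    build_graph,
    generate_cohort,
    optimize_lens,
    pairwise_distances,
    standardize_columns,
)
from syndromap.synthetic_cohort import SimulationConfig

warnings.filterwarnings("ignore", message="divide by zero")


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort under the default study conditions."""
    return generate_cohort(SimulationConfig(n_patients=586, seed=11))


@pytest.fixture(scope="session")
def default_distance(default_cohort):
    return pairwise_distances(standardize_columns(default_cohort))


@pytest.fixture(scope="session")
def default_lens(default_distance):
    return optimize_lens(default_distance)


@pytest.fixture(scope="session")
def default_graph(default_cohort, default_distance, default_lens):
    return build_graph(
        default_lens, default_distance, CoverConfig(), cohort=default_cohort
    )


@pytest.fixture
def small_cohort():
    return generate_cohort(SimulationConfig(n_patients=120, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
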