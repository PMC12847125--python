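import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from patchforage import (
    EnvLabel,
    LONG_BATTERY,
    MEAN_TIMING,
    OptimalSolver,
    SHORT_BATTERY,
)
from patchforage.synthetic_cohort import (
    CohortDesign,
    PopulationParams,
    generate_study_logs,
)


@pytest.fixture(scope="session")
def mean_solver() -> OptimalSolver:
    """Solver at the population-average timing, shared across tests."""
    return OptimalSolver(MEAN_TIMING)


@pytest.fixture(scope="session")
def conditions():
    return [
        (env, battery)
        for env in (EnvLabel.RICH, EnvLabel.MIXED)
        for battery in (LONG_BATTERY, SHORT_BATTERY)
    ]


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """Six optimal-play subjects, 2x6 trials each, no jitter: exact ground truth."""
    design = CohortDesign(n_subjects=6, trials_per_block=6)
    population = PopulationParams(beta=0.0, interval_jitter_sd=0.0)
    logs, cohort = generate_study_logs(design, population, seed=11)
    return logs, cohort


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """Eight softmax-noisy subjects with movement jitter, 2x8 trials each."""
    design = CohortDesign(n_subjects=8, trials_per_block=8)
    population = PopulationParams(beta=2.0, interval_jitter_sd=0.3)
    logs, cohort = generate_study_logs(design, population, seed=23)
    return logs, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
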