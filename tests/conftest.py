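import warnings

import numpy as np
import pytest

from adtraj import SimulationConfig, classify_cohort, screen_cohort, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort with 3 marker genes and a strong slope effect."""
    config = SimulationConfig(
        n_patients=80,
        n_controls=50,
        n_genes=150,
        n_marker_genes=3,
        slope_effect=0.2,
        seed=7,
    )
    return simulate_cohort(config), config


@pytest.fixture(scope="session")
def small_screen(small_cohort):
    """Labels and screening output for the compact cohort."""
    cohort, _ = small_cohort
    labels = classify_cohort(cohort.madrs)
    result = screen_cohort(cohort.counts, cohort.phenotypes, labels)
    return cohort, labels, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
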