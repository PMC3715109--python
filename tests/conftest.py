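import numpy as np
import pytest

from nmrfinger import CohortConfig, preprocess_spectra, response_effect_map, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 9-vs-7 synthetic cohort with the 4-metabolite response signature."""
    cfg = CohortConfig(group_sizes=(9, 7), effect_map=response_effect_map(1.0),
                       seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """The fully preprocessed (uncentered) feature matrix of small_cohort."""
    return preprocess_spectra(small_cohort.spectra)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
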