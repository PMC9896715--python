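import warnings

import pytest

from mrde import de
from mrde.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient, 400-gene cohort with planted structure (session cached)."""
    config = SimConfig(n_patients=12, n_genes=400)
    return simulate_cohort(config, seed=7), config


@pytest.fixture(scope="session")
def small_per_patient(small_cohort):
    (cm, samples, _, _), _ = small_cohort
    filtered = de.filter_genes(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return de.run_per_patient(filtered, samples)


@pytest.fixture(scope="session")
def small_all_patients(small_cohort):
    (cm, samples, _, _), _ = small_cohort
    filtered = de.filter_genes(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return de.run_all_patients(filtered, samples)
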