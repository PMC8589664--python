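import numpy as np
import pytest

from psystrat.mapper import MapperConfig, build_mapper_graph
from psystrat.simulate import default_params, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient default-parameter cohort with true labels."""
    params = default_params(n_patients=60, seed=42)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def medium_cohort():
    """300-patient default-parameter cohort with true labels."""
    params = default_params(n_patients=300, seed=7)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def medium_graph(medium_cohort):
    cohort, _ = medium_cohort
    return build_mapper_graph(cohort.panss, MapperConfig(), patient_ids=cohort.patient_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
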