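import numpy as np
import pytest

from moodhrv.cohort import apply_inclusion_filters, build_table
from moodhrv.inference import SamplerConfig, fit
from moodhrv.models import build_model
from moodhrv.synthetic import CohortConfig, generate_cohort

#: scaled-down sampler settings for replicate simulations in tests
FAST_SAMPLER = SamplerConfig(n_chains=2, n_tune=400, n_draws=400, target_accept=0.9, seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=1234))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    subjects, _ = default_cohort
    included, _ = apply_inclusion_filters(subjects)
    return build_table(included)


@pytest.fixture(scope="session")
def small_fit(default_table):
    """One fast one-disease fit on the default cohort, shared across tests."""
    spec = build_model(default_table, "one_disease")
    return fit(spec, default_table, FAST_SAMPLER)
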