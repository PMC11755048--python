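import numpy as np
import pytest
from hypothesis import settings

from niptsim import (
    CohortParams,
    SequencingParams,
    YBaselines,
    build_reference,
    generate_reference_cohort,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def seq() -> SequencingParams:
    return SequencingParams()


@pytest.fixture(scope="session")
def panel412(seq):
    """Euploid reference panel of 412 simulated samples (mixed fetal sex)."""
    return build_reference(generate_reference_cohort(412, seq, seed=11))


@pytest.fixture(scope="session")
def female_panel(seq):
    """Reference panel built from female-fetus euploid pregnancies only."""
    params = CohortParams(n_samples=412, seed=12, male_fraction=0.0)
    profiles = generate_reference_cohort(412, seq, seed=12, cohort_params=params)
    return build_reference(profiles)


@pytest.fixture(scope="session")
def baselines(seq) -> YBaselines:
    return YBaselines.from_sequencing_params(seq)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
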