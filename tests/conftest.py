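import numpy as np
import pytest

from neopkpd import (
    CohortSpec,
    SamplingScheme,
    final_model,
    generate_cohort,
    generate_dataset,
    make_record,
)


@pytest.fixture(scope="session")
def model():
    return final_model()


@pytest.fixture(scope="session")
def reference_covariates():
    """A neonate sitting exactly at the population median covariates."""
    return make_record(ga_weeks=36.5, pna_days=12.0, bw_g=2500.0, cw_g=2680.0)


@pytest.fixture(scope="session")
def sparse_study(model):
    """A 78-subject sparse opportunistic study simulated at the final model."""
    cohort = generate_cohort(CohortSpec(n_subjects=78, seed=3))
    return generate_dataset(cohort, model, seed=4)


@pytest.fixture(scope="session")
def rich_study(model):
    """100 subjects x 8 samples: a dense design for recovery experiments."""
    cohort = generate_cohort(CohortSpec(n_subjects=100, seed=21))
    return generate_dataset(cohort, model, SamplingScheme.rich(8), seed=22)
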