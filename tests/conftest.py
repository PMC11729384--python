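import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic survey, n=2000."""
    from pagsem import SyntheticConfig, generate_dataset

    return generate_dataset(SyntheticConfig(n_persons=2000), seed=101)


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    from pagsem import encode_study_covariates

    return encode_study_covariates(small_dataset.data)


@pytest.fixture(scope="session")
def latent_free_fit(small_encoded):
    """Covariate-only log-link Bernoulli fit on the small dataset."""
    from pagsem import FitOptions, fit_gsem
    from pagsem.model import DiseaseSpec, GsemSpec, STUDY_DISEASE_COVARIATES

    spec = GsemSpec(
        latents=(),
        disease=DiseaseSpec(outcome="obesity", covariates=STUDY_DISEASE_COVARIATES),
        weight_col="expansion_factor",
    )
    return spec, fit_gsem(spec, small_encoded, FitOptions())


@pytest.fixture(scope="session")
def small_joint_fit(small_encoded):
    """Full joint model fit on the small dataset (vcov included)."""
    from pagsem import FitOptions, default_study_spec, fit_gsem

    spec = default_study_spec()
    fitted = fit_gsem(spec, small_encoded, FitOptions(n_quad=15))
    return spec, fitted
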