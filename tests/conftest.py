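import numpy as np
import pandas as pd
import pytest

from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_questionnaire_fixture,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 200-patient cohort at the printed composition."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def psf_fm(default_cohort):
    """Raw (unscaled) PSF feature matrix of the default cohort."""
    return FeatureMatrix(values=default_cohort.psf_frame())


@pytest.fixture(scope="session")
def questionnaire():
    """The 283-patient raw questionnaire fixture."""
    return generate_questionnaire_fixture(seed=3)


@pytest.fixture(scope="session")
def outcome_task_frame(default_cohort):
    """The 7 modelled outcome columns of the default cohort."""
    return default_cohort.data[
        ["hypertension", "diabetes", "gestational_diabetes",
         "superimposed_pree", "severe_pree", "ga_delivery", "bmi"]
    ]
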