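import numpy as np
import pandas as pd
import pytest

from msverse import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 85-subject cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def medium_cohort():
    """Larger cohort for recovery-style checks."""
    return generate_cohort(CohortConfig(n_subjects=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_baseline(rng):
    """Small baseline-like frame with independent predictors."""
    n = 200
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "age": rng.normal(40, 8, n),
            "sex": rng.integers(0, 2, n),
            "dmt_followup": rng.integers(0, 2, n),
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
            "x3": rng.normal(0, 1, n),
        }
    )
    return df
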