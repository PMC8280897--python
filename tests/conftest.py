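import numpy as np
import pandas as pd
import pytest

from wbclung.synthetic import dftj_spec, generate_cohort

COVARIATES = ["age", "sex", "height", "smoking", "alcohol", "exercise"]


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 500-subject DFTJ-profile cohort reused by read-only tests."""
    return generate_cohort(dftj_spec(n_subjects=500, seed=20240101))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)


@pytest.fixture()
def regression_fixture(rng) -> pd.DataFrame:
    """20-row full-rank table with a known linear signal for oracle checks."""
    n = 20
    tab = pd.DataFrame(
        {
            "age": rng.normal(55, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "height": rng.normal(165, 7, n),
            "smoking": rng.integers(0, 2, n).astype(float),
            "alcohol": rng.integers(0, 2, n).astype(float),
            "exercise": rng.integers(0, 2, n).astype(float),
            "neutrophils": rng.lognormal(1.1, 0.3, n),
        }
    )
    tab["fvc"] = (
        3000
        - 30.0 * tab["neutrophils"]
        - 20.0 * tab["age"]
        + 35.0 * tab["height"]
        + rng.normal(0, 120, n)
    )
    return tab
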