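import numpy as np
import pytest

from healthdist import CohortConfig, DesignMatrix, DesignSpec, encode, simulate_cohort


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig(n=2000, seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    """Small synthetic cohort shared across tests."""
    return simulate_cohort(cohort_config)


@pytest.fixture(scope="session")
def cohort_design(cohort, cohort_config):
    """Design encoded with the generator's age centering, so fitted
    coefficients are directly comparable to the generating ones."""
    return encode(cohort, cohort_config.design_spec)


@pytest.fixture()
def intercept_design():
    """Intercept-only design over iid uniform responses."""

    def make(endog):
        endog = np.asarray(endog, dtype=float)
        return DesignMatrix(
            endog=endog,
            exog=np.ones((len(endog), 1)),
            columns=["const"],
            column_kind={"const": "intercept"},
            spec=DesignSpec(age_center=44.87),
        )

    return make
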