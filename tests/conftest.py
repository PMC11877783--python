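import pytest

from svztrace.categorize import categorize_patient
from svztrace.presence import call_patient
from svztrace.sim import cohort_fixture, gbm244_preset, simulate_patient


@pytest.fixture(scope="session")
def gbm244_noiseless():
    """The noiseless worked-example patient, simulated once per session."""
    return simulate_patient(gbm244_preset(noiseless=True))


@pytest.fixture(scope="session")
def gbm244_presence(gbm244_noiseless):
    ds = gbm244_noiseless
    return call_patient(ds.variants, ds.spec.manifest)


@pytest.fixture(scope="session")
def gbm244_categories(gbm244_presence):
    return categorize_patient(gbm244_presence)


@pytest.fixture(scope="session")
def cohort():
    """The packaged 10-patient fixture cohort."""
    return cohort_fixture()
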