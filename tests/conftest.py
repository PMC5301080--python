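import pytest

from psyrx.atc import default_registry
from psyrx.io import load_cohort, reference_regimens, reference_utilization
from psyrx.reports import analyze_cohort
from psyrx.simulate import fixture_table2_cohort, fixture_table3_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reference_table():
    """Published per-drug utilization reference rows (18 presentations)."""
    return reference_utilization()


@pytest.fixture(scope="session")
def reference_regimen_table():
    return reference_regimens()


@pytest.fixture(scope="session")
def table3_cohort(registry):
    patients, diagnoses, prescriptions = fixture_table3_cohort()
    return load_cohort(patients, diagnoses, prescriptions, registry)


@pytest.fixture(scope="session")
def table3_report(table3_cohort, registry):
    return analyze_cohort(table3_cohort, registry)


@pytest.fixture(scope="session")
def table2_cohort(registry):
    patients, diagnoses, prescriptions = fixture_table2_cohort()
    return load_cohort(patients, diagnoses, prescriptions, registry)
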