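import pytest

from lnfnac import CostSchedule, reference_cohort, run_model, tally_cohort


@pytest.fixture(scope="session")
def cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def tallies(cohort):
    return tally_cohort(run_model(cohort), cohort)


@pytest.fixture(scope="session")
def schedule():
    return CostSchedule()
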