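import pytest

from asecall.synthetic import FIXTURE_A, FIXTURE_B, simulate_cohort


@pytest.fixture(scope="session")
def fixture_a_sim():
    """Reference cohort A: 63 controls, 103 balanced + 17 planted ASE cases."""
    return simulate_cohort(FIXTURE_A)


@pytest.fixture(scope="session")
def fixture_b_sim():
    """Reference cohort B: 110 balanced + 10 planted ASE cases, no controls."""
    return simulate_cohort(FIXTURE_B)
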