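import pytest
from hypothesis import HealthCheck, settings

import evotherapy as et

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def patient1():
    return et.table3_patient(1)


@pytest.fixture(scope="session")
def patient2():
    return et.table3_patient(2)


ALL_REGIMENS = {
    "untreated": et.RegimenSpec.untreated,
    "mtd": et.RegimenSpec.mtd,
    "metronomic": et.RegimenSpec.metronomic,
    "adaptive": et.RegimenSpec.adaptive,
}


@pytest.fixture(scope="session")
def p1_results(patient1):
    """Patient 1 simulated under all four regimens with default settings."""
    return {k: et.simulate(patient1, mk(), inoculum=1.0)
            for k, mk in ALL_REGIMENS.items()}


@pytest.fixture(scope="session")
def p2_results(patient2):
    """Patient 2 simulated under all four regimens with default settings."""
    return {k: et.simulate(patient2, mk(), inoculum=1.0)
            for k, mk in ALL_REGIMENS.items()}
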