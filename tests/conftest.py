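import pytest
from hypothesis import HealthCheck, settings

from biofiltersim import compute_gammas, fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=75,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def benzene_compound():
    return fixtures.benzene_compound()


@pytest.fixture(scope="session")
def benzene_biofilm():
    return fixtures.benzene_biofilm()


@pytest.fixture(scope="session")
def benzene_bed():
    return fixtures.benzene_bed()


@pytest.fixture(scope="session")
def benzene_derived(benzene_compound, benzene_biofilm, benzene_bed):
    return compute_gammas(benzene_compound, benzene_biofilm, benzene_bed)
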