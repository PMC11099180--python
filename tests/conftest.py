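import pytest
from hypothesis import HealthCheck, settings

import orglattice as ol
from orglattice.datasets import theorem1_network, theorem2_network

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def theorem1():
    return theorem1_network()


@pytest.fixture(scope="session")
def theorem2():
    return theorem2_network()


@pytest.fixture()
def abc_universe():
    return ol.TaxaUniverse(["a", "b", "c", "x", "y"])


@pytest.fixture()
def motif_table(abc_universe):
    """Four measurements whose closure holds one additional organization
    ({a,b,c} = {a,b,c,x} ∩ {a,b,c,y} = {a,b} ∪ {a,c})."""
    u = abc_universe
    sets = [u.set_of("ab"), u.set_of("ac"), u.set_of("abcx"), u.set_of("abcy")]
    samples = [
        ol.SampleRecord(f"H41:{i}", "H41", i, s) for i, s in enumerate(sets)
    ]
    return ol.MeasurementTable(u, samples)
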