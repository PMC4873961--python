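import pytest

from cmodel.simulate import SimulationConfig, make_fixture, simulate


@pytest.fixture(scope="session")
def tiny_ds():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def reference_table_ds():
    return make_fixture("reference_table")


@pytest.fixture(scope="session")
def heterogeneous_ds():
    return make_fixture("heterogeneous_facilities")


@pytest.fixture(scope="session")
def sim_small():
    """2 facilities x 1,000 women simulated from v1.0 truth."""
    return simulate(SimulationConfig(n_facilities=2, n_per_facility=1000, seed=42))


@pytest.fixture(scope="session")
def sim_medium():
    """5 facilities x 2,000 women simulated from v1.0 truth."""
    return simulate(SimulationConfig(n_facilities=5, n_per_facility=2000, seed=7))
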