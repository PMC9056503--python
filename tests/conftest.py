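import numpy as np
import pytest

from actipet.stopping import load_table
from actipet.synthetic import ScenarioSpec


@pytest.fixture(scope="session")
def water():
    return load_table("water")


@pytest.fixture(scope="session")
def air():
    return load_table("air")


@pytest.fixture(scope="session")
def kapton():
    return load_table("kapton")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_scenario():
    """A light scenario (tens of cps) for event-level tests, to keep the
    simulated streams small."""
    return ScenarioSpec(
        name="small",
        amplitudes_cps={"18F": 40.0, "11C": 8.0, "13N": 3.0},
        f18O=0.02,
        background_cps=0.5,
        seed=7,
    )
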