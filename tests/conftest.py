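import numpy as np
import pytest

from tavicea import load_parameter_set

@pytest.fixture(scope="session")
def intermediate_base():
    return load_parameter_set("intermediate_base")


@pytest.fixture(scope="session")
def high_base():
    return load_parameter_set("high_base")


@pytest.fixture(scope="session")
def inoperable_base():
    return load_parameter_set("inoperable_base")


@pytest.fixture(scope="session")
def intermediate_micro():
    return load_parameter_set("intermediate_micro")


@pytest.fixture(scope="session")
def intermediate_short():
    """Intermediate-risk inputs on a 5-year horizon: same structure, much
    faster to rerun many times (sensitivity tests).  Treat as read-only;
    copy before mutating."""
    return load_parameter_set(
        "intermediate_base", overrides={"settings": {"horizon_cycles": 60}}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
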