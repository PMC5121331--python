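import numpy as np
import pytest

import clonedd as cd


@pytest.fixture(scope="session")
def assay_table():
    """One standard simulated four-condition assay, shared across tests."""
    return cd.simulate_clone_table(cd.default_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
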