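import logging

import numpy as np
import pytest

from ltpminer.classification import load_rules
from ltpminer.synthetic_data import SimPlan, simulate_dataset

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic study (two diploids + allotetraploid), shared
    across tests; regenerating it is deterministic."""
    return simulate_dataset(SimPlan(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
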