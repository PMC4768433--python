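import numpy as np
import pytest

from nlamd.datasets import random_molecule, worked_example


@pytest.fixture(scope="session")
def we():
    """The chloro(methoxy)methane reference fixture."""
    return worked_example()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture
def mol5():
    return random_molecule(5, seed=7)
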