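import numpy as np
import pytest

from betadrivers import SynthSpec, simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    """One default 50-site study bundle shared across tests."""
    return simulate_dataset(SynthSpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
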