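import numpy as np
import pytest

from dupreloc.aamodels import jtt_model


@pytest.fixture(scope="session")
def jtt():
    return jtt_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
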