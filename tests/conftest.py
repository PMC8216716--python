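import numpy as np
import pytest

from gripdcm.neuralmass import default_model


@pytest.fixture(scope="session")
def freqs():
    return np.arange(4.0, 49.0)


@pytest.fixture(scope="session")
def model():
    return default_model()
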