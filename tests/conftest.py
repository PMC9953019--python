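import numpy as np
import pytest

import pulsewss as pw


@pytest.fixture(scope="session")
def responses():
    """All 14 packaged response variables in one long table."""
    return pw.load_all_responses()


@pytest.fixture(scope="session")
def waveform():
    """Default cardiac waveform (1 s cycle, 200 samples)."""
    return pw.make_waveform()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
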