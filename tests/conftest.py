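import numpy as np
import pytest

from hampulse import standard_pulse

TWO_PI = 2.0 * np.pi


@pytest.fixture(scope="session")
def rect_hard():
    """25 kHz / 10 us rectangular 90-degree pulse."""
    return standard_pulse("rect_hard")


@pytest.fixture(scope="session")
def rect_soft():
    """250 Hz / 1 ms rectangular 90-degree pulse."""
    return standard_pulse("rect_soft")


@pytest.fixture(scope="session")
def eburp2():
    return standard_pulse("eburp2")


@pytest.fixture(scope="session")
def reburp():
    return standard_pulse("reburp")


@pytest.fixture(scope="session")
def q5_pulse():
    return standard_pulse("q5")


@pytest.fixture(scope="session")
def wurst20():
    return standard_pulse("wurst20")
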