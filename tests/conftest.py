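import numpy as np
import pytest

from cryptometry import phantom


@pytest.fixture(scope="session")
def bundle():
    """Default three-focus phantom (round/slit/spiral crypts, one GALT
    region, stage shift (7, -3)) shared across read-only tests."""
    return phantom.gen_wholemount(phantom.default_spec(1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
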