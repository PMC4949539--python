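import numpy as np
import pytest

from neomyelin.diffusion import two_shell_protocol


@pytest.fixture(scope="session")
def protocol():
    """The two-shell acquisition used throughout: 1 b0 + 16 b750 + 32 b2000."""
    return two_shell_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160321)
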