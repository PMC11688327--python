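import numpy as np
import pytest

from somnostage.synthetic import default_templates, generate_recording


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def small_recording():
    """A 40-epoch synthetic night shared by I/O round-trip tests."""
    return generate_recording(n_epochs=40, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
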