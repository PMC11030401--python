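import numpy as np
import pytest

from eventshift.layout import make_session_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_run_layout():
    """Four 150 s movies in two runs; TR 1.5 s; 4 s titles."""
    return make_session_layout(
        [150.0, 150.0, 150.0, 150.0], title_duration=4.0, tr=1.5,
        runs=[(0, 1), (2, 3)],
    )


@pytest.fixture
def single_run_layout():
    return make_session_layout([120.0, 120.0], title_duration=4.0, tr=1.5)
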