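import warnings

import pytest

from hjsmc.engine import run_free
from hjsmc.parameters import load_parameters
from hjsmc.stimulus import default_stimulus

warnings.filterwarnings("ignore", message=".*45-fold.*")


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def stimulus(params):
    return default_stimulus(params.document)


@pytest.fixture(scope="session")
def default_trace(params, stimulus):
    """The canonical 180 s free run (0.1 ms step, 60 s burn-in), shared by
    every test that inspects default slow-wave behaviour."""
    return run_free(params, stimulus, duration=180000.0)
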