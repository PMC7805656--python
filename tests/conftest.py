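import numpy as np
import pytest

from fmgforce import BandLayout, CouplingModel, ProtocolConfig, generate_subject


@pytest.fixture(scope="session")
def layout():
    return BandLayout()


@pytest.fixture(scope="session")
def short_cfg():
    """Reduced-duration protocol for fast unit tests (8 s sessions)."""
    return ProtocolConfig(n_trials=3, session_duration_s=8.0)


@pytest.fixture(scope="session")
def default_cfg():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def coupling(layout):
    return CouplingModel.default(layout, seed=7)


@pytest.fixture(scope="session")
def small_subject(short_cfg, coupling, layout):
    """3 trials x 7 sessions x 80 samples; fast enough for pipeline tests."""
    return generate_subject(short_cfg, coupling, layout, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
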