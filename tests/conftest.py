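import numpy as np
import pytest

from drowsyte.pipeline import PipelineConfig, preprocess_session
from drowsyte.synth import CouplingTruth, SessionConfig, gen_session


@pytest.fixture(scope="session")
def small_session():
    """60-trial synthetic session with one inverted-U and one monotone
    coupling, shared across tests (generation ~1 s)."""
    cfg = SessionConfig(n_trials=60, seed=11)
    truths = (
        CouplingTruth("Cz", "Pz", lag=10, strength=0.8, shape="inverted_u"),
        CouplingTruth("Pz", "Oz", lag=10, strength=0.8,
                      shape="monotone_decreasing"),
    )
    session, beh = gen_session(cfg, truths)
    return session, beh, truths


@pytest.fixture(scope="session")
def small_epochs(small_session):
    session, beh, truths = small_session
    epochs = preprocess_session(session, PipelineConfig())
    return epochs, beh


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
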