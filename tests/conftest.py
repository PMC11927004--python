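import warnings

import numpy as np
import pytest

from cwcst.evaluate import ExperimentConfig, prepare_session
from cwcst.models import TrainConfig
from cwcst.simulate import default_simulation, generate_session


@pytest.fixture(scope="session")
def mini_session():
    """A reduced synthetic session shared by the slower integration tests.

    Same protocol structure as the default study (9 gestures + rest, rest
    last, randomised order, one calibration trial) at a fraction of the
    duration so the suite stays fast.
    """
    cfg = default_simulation(
        seed=11, n_per_gesture=6,
        motion_duration_s=3.0, rest_duration_s=1.5, n_trials=4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, truths = generate_session(cfg)
    return cfg, session, truths


@pytest.fixture(scope="session")
def mini_prepared(mini_session):
    """Decomposition model + framed features for the mini session."""
    _, session, _ = mini_session
    exp = ExperimentConfig(training=TrainConfig(epochs=8, seed=5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared = prepare_session(session, exp)
    return exp, prepared


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
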