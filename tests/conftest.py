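import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from gazehmi import (DetectionSettings, KinematicParams, LearnerState,
                     SceneGeometry, SessionLayout)


@pytest.fixture(scope="session")
def scene():
    return SceneGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_layout():
    """A short session that keeps all four learning phases."""
    return SessionLayout(n_pre=4, n_feedback=16, n_post=4, phase_window=4)


@pytest.fixture(scope="session")
def noiseless_kinematics():
    return KinematicParams(endpoint_noise_sd=0.0, aim_noise_sd=0.0,
                           p_secondary=0.0)
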