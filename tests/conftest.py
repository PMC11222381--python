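import numpy as np
import pytest

from bbbflow.phantom import (
    AcquisitionParams,
    default_flow_truth,
    default_ground_truth,
    make_brain_phantom,
    make_flow_phantom,
    simulate_dce,
    simulate_vfa,
)


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def truth3():
    return default_ground_truth(3)


@pytest.fixture(scope="session")
def brain(params, truth3):
    return make_brain_phantom((32, 32, 32), params, truth3, seed=0)


@pytest.fixture(scope="session")
def vfa_noiseless(brain, params):
    return simulate_vfa(brain, params)


@pytest.fixture(scope="session")
def dce_noiseless(brain, truth3, params):
    return simulate_dce(brain, truth3, params)


@pytest.fixture(scope="session")
def flow_phantom(params):
    truth = default_flow_truth(params.n_cardiac_frames)
    return make_flow_phantom(truth, (44, 44, 44), 0.6875, params, seed=0)


@pytest.fixture(scope="session")
def vif_curve(truth3, params):
    times = params.frame_times
    return times, truth3.vif.concentration(
        times, truth3.injection_start, truth3.injection_duration
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
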