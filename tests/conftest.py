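import numpy as np
import pytest

import servonav as sv


@pytest.fixture(scope="session")
def phantom():
    return sv.default_head_phantom()


@pytest.fixture(scope="session")
def coil():
    return sv.CoilModel.synthetic(8)


@pytest.fixture(scope="session")
def traj():
    return sv.make_orbital()


@pytest.fixture(scope="session")
def clean_model(phantom, coil, traj):
    """Linear model calibrated without noise on the default geometry."""
    cal = sv.acquire_calibration(phantom, coil, traj, noise_sd=0.0, seed=0)
    return sv.build_model(cal, traj)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
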