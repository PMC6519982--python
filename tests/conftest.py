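import numpy as np
import pytest

from vesiclekit import ReleaseModelParams, make_protocol
from vesiclekit.kinetics import RecruitmentRateFunction


@pytest.fixture
def calyx_rec():
    return RecruitmentRateFunction(alpha_0=5.4, alpha_inf=1.5, tau_alpha=2.0,
                                   alpha_train=5.0)


@pytest.fixture
def calyx_params(calyx_rec):
    """Single-class calyx-like pool, convenient for closed-form checks."""
    return ReleaseModelParams(n_high=4000, n_low=0, pv_high=0.1, pv_low=0.0,
                              recruitment=calyx_rec)


@pytest.fixture
def train_300hz():
    return make_protocol([(300.0, 90)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
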