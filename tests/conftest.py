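import numpy as np
import pytest

from triguild import ModelParams, generate_community


@pytest.fixture
def params():
    return ModelParams()


def make_system(seed=0, S=6, omega=(0.05, 0.1, 0.1), C=0.3, **kwargs):
    """Small random community used across test modules."""
    params = ModelParams(
        omega_c=omega[0], omega_p=omega[1], omega_m=omega[2],
        C_mut=C, C_ant=C, **kwargs,
    )
    mats = generate_community(
        params, S_P=S, S_M=S, S_H=S, seed=np.random.SeedSequence(seed))
    return mats, params
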