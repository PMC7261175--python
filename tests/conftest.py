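import numpy as np
import pytest

from smfretpop import EmissionParams, KineticParams, simulate_dataset


@pytest.fixture
def static_mixture():
    """Small static 50/50 open-closed dataset with default emission."""
    kin = KineticParams(k_oc=0.0, k_co=0.0)
    emi = EmissionParams()
    ts, gt = simulate_dataset(kin, emi, 60, 0.0, seed=20240901, p_closed=0.5)
    return ts, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
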