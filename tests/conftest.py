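import numpy as np
import pytest

from larex import bm_sim as bm
from larex import experiments as ex
from larex import omega as om

FIG5_FB = 1.8e-3
FIG5_KBA = 400.0


@pytest.fixture(scope="session")
def arex_config():
    return om.ArexConfig.from_scheme(bm.scheme_3t(1.0))


@pytest.fixture(scope="session")
def fig5_stack6():
    """Six-pool disc stack at the worked-example operating point, 7 B1 levels."""
    return ex.simulate_stack(bm.ivd6(FIG5_FB, FIG5_KBA))


@pytest.fixture(scope="session")
def fig5_stack2():
    """Matching ideal two-pool stack (water + hydroxyl only)."""
    return ex.simulate_stack(bm.ideal2(FIG5_FB, FIG5_KBA))


@pytest.fixture(scope="session")
def water_system():
    return bm.PoolSystem((bm.Pool("water", bm.WATER_T1_S, bm.WATER_T2_S),))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220622)
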