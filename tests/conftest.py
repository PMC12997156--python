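import numpy as np
import pytest

from cuprelax import SpinSystemCu
from cuprelax.presets import (
    CU_TACN,
    CU_TREN_PH7,
    CU_TREN_PH12,
    SPIN_TACN,
    SPIN_TREN,
)


@pytest.fixture
def tacn_spin():
    return SpinSystemCu(g=SPIN_TACN["g"], A_Cu=SPIN_TACN["A_Cu"])


@pytest.fixture
def tren_spin():
    return SpinSystemCu(g=SPIN_TREN["g"], A_Cu=SPIN_TREN["A_Cu"])


@pytest.fixture(params=["cu_tacn", "cu_tren_ph7", "cu_tren_ph12"])
def preset(request):
    return {
        "cu_tacn": CU_TACN,
        "cu_tren_ph7": CU_TREN_PH7,
        "cu_tren_ph12": CU_TREN_PH12,
    }[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
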