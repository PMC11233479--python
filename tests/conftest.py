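import math

import numpy as np
import pytest

from ktmese.epg import build_dictionary, default_b1_grid, default_t2_grid
from ktmese.protocols import AcquisitionProtocol, bh_protocol, high_res_protocol


@pytest.fixture(scope="session")
def bh_prot():
    return bh_protocol()


@pytest.fixture(scope="session")
def hr_prot():
    return high_res_protocol()


@pytest.fixture(scope="session")
def hr_prot_small(hr_prot):
    """High-resolution echo train on the 128×128 test grid."""
    return AcquisitionProtocol(
        name="high_res",
        esp_ms=hr_prot.esp_ms,
        n_echoes=hr_prot.n_echoes,
        tr_ms=math.inf,
        refoc_schedule_deg=hr_prot.refoc_schedule_deg,
        matrix=(128, 128),
    )


@pytest.fixture(scope="session")
def cpmg_prot():
    """Ideal 180° refocusing train for closed-form checks."""
    return AcquisitionProtocol(
        name="cpmg",
        esp_ms=10.0,
        n_echoes=3,
        tr_ms=math.inf,
        refoc_schedule_deg=(180.0, 180.0, 180.0),
        matrix=(64, 64),
    )


@pytest.fixture(scope="session")
def bh_dictionary(bh_prot):
    return build_dictionary(default_t2_grid(), default_b1_grid(), 1500.0, bh_prot)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240710)
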