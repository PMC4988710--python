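import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cc36():
    from soxdimer.synthetic_data import bundled_probes

    return bundled_probes()["CC36"]


@pytest.fixture
def s9wt():
    from soxdimer.synthetic_data import bundled_probes

    return bundled_probes()["S9WT"]


@pytest.fixture
def dimer_region():
    from soxdimer.seqtools import ProteinRegion

    return ProteinRegion("SIREAVSQVLSGY", start=72, label="alpha0")


@pytest.fixture(scope="session")
def toy_fold():
    from soxdimer.synthetic_data import toy_hmg

    return toy_hmg()


@pytest.fixture(scope="session")
def alpha0_helix():
    from soxdimer.synthetic_data import DIMERIZATION_SEQUENCE, ideal_helix

    return ideal_helix(DIMERIZATION_SEQUENCE, 71, "A")
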