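import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bzdna.fiber import build_fiber_duplex

#: duplex with only canonical pairs (d(CAA)5 analog of the control scheme)
WC_SEQUENCE = "CAACAACAACAACAA"


@pytest.fixture(scope="session")
def wc_duplex():
    return build_fiber_duplex(WC_SEQUENCE)


@pytest.fixture(scope="session")
def mm_duplex():
    """Duplex with a single A...A mismatch opposite residue 8."""
    return build_fiber_duplex(WC_SEQUENCE, mismatches={8: "A"})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
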