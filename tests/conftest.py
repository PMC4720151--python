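import pytest

from bcellfate import ContinuousParams, enumerate_attractors, load_bcell_network

# Core-module patterns of the four wild-type cell fates, ordered
# [Bach2, Bcl6, Blimp1, Irf4, Pax5, XBP1].
CORE_PATTERNS = {
    "Naive": (1, 0, 0, 0, 1, 0),
    "GC": (1, 1, 0, 0, 1, 0),
    "Mem": (1, 0, 0, 1, 1, 0),
    "PC": (0, 0, 1, 1, 0, 1),
}


@pytest.fixture(scope="session")
def bcell():
    return load_bcell_network()


@pytest.fixture(scope="session")
def wt_attractors(bcell):
    """Exhaustive synchronous enumeration of the wild-type model (2^22)."""
    return enumerate_attractors(bcell)


@pytest.fixture(scope="session")
def params():
    return ContinuousParams()
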