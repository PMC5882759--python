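import pytest

from psirr import crypto

# Printed per-class cells (label -> (cases, non-cases)); L is the reference.
MEN_CELLS = {"L": (79, 13915), "S": (36, 8229), "T": (25, 7865), "H": (32, 9830)}
WOMEN_CELLS = {"L": (40, 14347), "S": (32, 11703), "T": (32, 10283), "H": (19, 8473)}

MEN_EXPECTED = {"L": (1.00, None), "S": (0.77, 1.68), "T": (0.56, 6.54), "H": (0.57, 7.20)}
WOMEN_EXPECTED = {"L": (1.00, None), "S": (0.98, 0.01), "T": (1.12, 0.21), "H": (0.80, 0.61)}


@pytest.fixture(scope="session")
def toy_params():
    """Hand-checkable group: p=23, q=11, cofactor=2."""
    return crypto.GroupParams.from_pq(23, 11)


@pytest.fixture(scope="session")
def small_params():
    """96/48-bit group: fast modular arithmetic, negligible collision risk."""
    return crypto.generate_params(96, 48, rng_seed=1234)
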