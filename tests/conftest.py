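import numpy as np
import pytest

from cperegnet.io import UTRRecord

# AlphaScreen CPE-A / CPE-G oligos (28 nt of the cyclin B1 3' UTR)
CPE_A_OLIGO = "AGUGUACAGUGUUUUUAAUAGUUUGUUG"
CPE_G_OLIGO = "AGUGUACAGUGUUUUUGUAAGUUUGUUG"


@pytest.fixture
def cpe_a_record() -> UTRRecord:
    return UTRRecord("cpe_a", CPE_A_OLIGO)


@pytest.fixture
def cpe_g_record() -> UTRRecord:
    return UTRRecord("cpe_g", CPE_G_OLIGO)


def random_records(rng: np.random.Generator, n: int, length, prefix: str = "s", p_u: float = 0.25):
    """Random RNA records; ``length`` is an int or (lo, hi) range."""
    p = np.array([(1 - p_u) / 3] * 3 + [p_u])
    out = []
    for i in range(n):
        L = length if isinstance(length, int) else int(rng.integers(length[0], length[1] + 1))
        out.append(UTRRecord(f"{prefix}{i}", "".join(rng.choice(list("ACGU"), L, p=p))))
    return out
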