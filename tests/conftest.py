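import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from icp import make_locus

BASES = np.array(list("ACGT"))


def random_ref(rng, n):
    return "".join(rng.choice(BASES, n))


def random_locus(rng, n=100, cut_at=None, primer_len=12):
    """Random amplicon locus with the protospacer placed so the cut lands
    mid-amplicon (default at position n//2 with cut_offset 3)."""
    cut = cut_at if cut_at is not None else n // 2
    pam_start = cut + 3
    ref = random_ref(rng, n)
    return make_locus(
        ref,
        protospacer_interval=(pam_start - 20, pam_start),
        pam_interval=(pam_start, pam_start + 3),
        primer_intervals=((0, primer_len), (n - primer_len, n)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def locus(rng):
    """One fixed 100-nt locus, cut at 50, 12-nt primers at both ends."""
    return random_locus(np.random.default_rng(7))
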