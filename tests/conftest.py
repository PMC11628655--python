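import numpy as np
import pytest
from hypothesis import settings

from karyokit.model import GenomeAssembly, Karyotype, SignedFragment

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_assembly():
    return GenomeAssembly("toy", [("c1", 6_000_000), ("c2", 5_000_000),
                                  ("c3", 4_000_000), ("c4", 5_000_000)])


@pytest.fixture
def three_frag_karyotype():
    """One chromosome of three 1-Mb fragments, its own reference."""
    return Karyotype("root", {"chr1": [SignedFragment("chr1", 0, 3_000_000, 1)]})


def random_intervals(rng, assembly, n, length):
    """Uniformly placed fixed-length intervals (may overlap)."""
    chroms = assembly.chromosomes
    out = []
    for _ in range(n):
        ci = int(rng.integers(len(chroms)))
        cid, clen = chroms[ci]
        s = int(rng.integers(0, clen - length))
        out.append((cid, s, s + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
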