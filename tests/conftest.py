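import numpy as np
import pytest

from tecurate._dna import revcomp
from tecurate.simulator import FamilySpec, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def small_sim():
    """One TIR/TSD family implanted in a 120 kb genome."""
    fam = FamilySpec(name="famA", length=800, classification="DNA/hAT",
                     tir_len=12, tsd_len=5, copy_number=15, divergence=0.08,
                     truncation_prob=0.1)
    return simulate_genome([fam], background_len=120_000, seed=7)


def truth_flanks(sim, flank=40):
    """(left, element, right) per copy, oriented, from truth coordinates."""
    out = []
    for t in sim.truth:
        g = sim.contigs[t.contig]
        left, elem, right = (g[t.start - flank:t.start],
                             g[t.start:t.end], g[t.end:t.end + flank])
        if t.strand == "-":
            left, elem, right = revcomp(right), revcomp(elem), revcomp(left)
        out.append((left, elem, right))
    return out
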