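"""Self-contained recovery studies: simulate, curate, measure.

These drive both the test suite and the reproduction script: every number
is recomputed at call time by running the full pipeline on freshly
simulated data. Study conditions follow the simulator defaults (800 bp
elements carrying 12 bp TIRs, 15 copies at 8% expected divergence with 10%
of copies 5'-truncated, TSDs of 4-8 bp, 2 kb flank extension of the best
20 hits); problem sizes are chosen to keep a full study in the
low minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tecurate.align import align
from tecurate.annotation_stats import kimura2p
from tecurate.seqio import ConsensusRecord
from tecurate.simulator import (
    FamilySpec, make_raw_consensus, mutate_copy, simulate_genome,
)
from tecurate.pipeline import curate_from_genome


@dataclass
class FamilyOutcome:
    seed: int
    tsd_len_true: int
    identity: float
    coverage: float
    boundary_error: int
    tsd_len_called: int | None
    length_delta: int


def run_family(seed: int, tsd_len: int | None = None,
               background_len: int = 120_000) -> FamilyOutcome:
    """Simulate one family, curate it from a truncated noisy draft, and
    score the result against the known element."""
    tl = tsd_len if tsd_len is not None else 4 + seed % 5
    fam = FamilySpec(name="fam", length=800, classification="DNA/hAT",
                     tir_len=12, tsd_len=tl, copy_number=15, divergence=0.08,
                     truncation_prob=0.1)
    sim = simulate_genome([fam], background_len=background_len, seed=seed)
    elem = sim.elements["fam"]
    rng = np.random.default_rng(seed)
    raw = ConsensusRecord(id="fam", sequence=make_raw_consensus(elem, rng))
    result = curate_from_genome(raw, sim.contigs)
    rec = result.curation.record
    r = align(rec.sequence, elem, mode="glocal")
    coverage = (r.b_end - r.b_start) / len(elem)
    boundary = max(r.b_start, len(elem) - r.b_end,
                   r.a_start, len(rec) - r.a_end)
    tsd = result.hallmarks.tsd
    return FamilyOutcome(
        seed=seed, tsd_len_true=tl, identity=r.identity, coverage=coverage,
        boundary_error=boundary,
        tsd_len_called=tsd.consensus_length if tsd else None,
        length_delta=len(rec) - len(raw))


def recovery_study(n_families: int = 50, seed: int = 0) -> dict:
    """End-to-end recovery rates over seeded synthetic families."""
    outcomes = [run_family(seed * 10_007 + i) for i in range(n_families)]
    n = len(outcomes)
    return {
        "n_families": n,
        "consensus_recovery_rate": sum(
            o.identity >= 0.95 and o.coverage >= 0.95 for o in outcomes) / n,
        "boundary_within_10bp_rate": sum(
            o.boundary_error <= 10 for o in outcomes) / n,
        "tsd_length_exact_rate": sum(
            o.tsd_len_called == o.tsd_len_true for o in outcomes) / n,
        "median_length_delta": float(np.median(
            [o.length_delta for o in outcomes])),
        "mean_identity": float(np.mean([o.identity for o in outcomes])),
    }


def tc4_study(seed: int = 0, copy_number: int = 20) -> dict:
    """Recover the interrupted-palindrome target site of a Tc4-style
    family (CTNAG cut between C and G, central TNA duplicated) from
    truth-annotated insertions."""
    from tecurate._dna import revcomp
    from tecurate.hallmarks import find_tsd, fit_target_site_model

    fam = FamilySpec(name="tc4", length=600, classification="DNA/TcMar-Tc4",
                     tir_len=10, tsd_len=3, target_site_pattern="C[TNA]G",
                     copy_number=copy_number, divergence=0.02,
                     truncation_prob=0.0)
    sim = simulate_genome([fam], background_len=180_000, seed=seed)
    g = sim.contigs[sim.truth[0].contig]
    flanks = []
    for t in sim.truth:
        left, elem, right = (g[t.start - 40:t.start], g[t.start:t.end],
                             g[t.end:t.end + 40])
        if t.strand == "-":
            left, elem, right = revcomp(right), revcomp(elem), revcomp(left)
        flanks.append((left, elem, right))
    rep = find_tsd(flanks)
    model = fit_target_site_model(rep, flanks)
    return {
        "tsd_length": rep.consensus_length,
        "motif": rep.motif,
        "target_site": model.annotated if model else None,
    }


def kimura_recovery(seed: int = 0, divergence: float = 0.10,
                    n_copies: int = 50, length: int = 5000) -> dict:
    """K2P parameter recovery: decay copies under the two-rate process and
    re-estimate the distance; the closed form applied to the target
    transition/transversion proportions is the expectation."""
    rng = np.random.default_rng(seed)
    elem = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    ks = []
    for _ in range(n_copies):
        mut = mutate_copy(elem, divergence, 2.0, rng)
        ks.append(kimura2p(mut.p, mut.q))
    ks = np.array(ks)
    expected = kimura2p(divergence * 2 / 3, divergence / 3)
    se = ks.std(ddof=1) / np.sqrt(len(ks))
    return {
        "mean_k": float(ks.mean()),
        "expected_k": float(expected),
        "z": float((ks.mean() - expected) / se),
        "n_copies": n_copies,
    }
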