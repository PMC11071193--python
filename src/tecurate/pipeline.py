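"""The full curation loop: mine -> extend -> align -> consensus, iterated.

A single curation pass already recovers sequence missing from a truncated
draft, but that recovered sequence enters the alignment through insertion
blocks whose per-copy alignment quality is below that of the anchored
columns. Re-running the loop with the improved consensus as the anchor —
exactly how curators iterate Blast-Extend-Extract until the consensus
stops changing — aligns every copy against a full-length anchor and gives
clean per-copy termini for hallmark detection. Two rounds are almost
always enough; iteration stops early when the consensus converges.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass

from tecurate.align import align
from tecurate.consensus_builder import CurationResult, curate
from tecurate.copy_miner import extract_oriented, find_copies, select_and_extend
from tecurate.hallmarks import HallmarkReport, hallmark_report
from tecurate.seqio import ConsensusRecord


@dataclass
class PipelineResult:
    curation: CurationResult
    hallmarks: HallmarkReport
    rounds_run: int
    n_hits: int


def curate_from_genome(raw: ConsensusRecord, genome, rounds: int = 2,
                       top_n: int = 20, flank: int = 2000,
                       min_score: int = 30, **curate_kwargs) -> PipelineResult:
    """Run the mine/extend/extract/curate loop against a genome.

    Each round searches the genome with the current consensus, extends the
    best `top_n` hits by `flank` bp, rebuilds the anchored alignment and
    recomputes the majority-rule consensus. Returns the final curation plus
    a hallmark report built from the final per-copy flanks.
    """
    contigs = dict(genome) if not isinstance(genome, dict) else genome
    lengths = {c: len(s) for c, s in contigs.items()}
    anchor = raw
    result = None
    n_hits = 0
    rounds_run = 0
    for _ in range(max(1, rounds)):
        hits = find_copies(anchor, contigs, min_score=min_score)
        if not hits:
            raise ValueError(f"{raw.id}: no genomic copies found")
        n_hits = len(hits)
        intervals = select_and_extend(hits, n=top_n, flank=flank,
                                      contig_lengths=lengths)
        copies = extract_oriented(contigs, intervals)
        result = curate(anchor, copies, **curate_kwargs)
        rounds_run += 1
        if result.record.sequence == anchor.sequence:
            break
        anchor = result.record
    seq = result.record.sequence
    cwf = refine_flanks(seq, copies)
    extended = extend_from_flanks(seq, cwf)
    if extended != seq:
        result = dataclasses.replace(
            result, record=dataclasses.replace(result.record,
                                               sequence=extended))
        cwf = refine_flanks(extended, copies)
    report = hallmark_report(result.record.sequence, cwf)
    return PipelineResult(curation=result, hallmarks=report,
                          rounds_run=rounds_run, n_hits=n_hits)


def extend_from_flanks(consensus: str, copies_with_flanks,
                       max_extension: int = 100, min_depth_frac: float = 0.6,
                       min_agree: float = 0.6) -> str:
    """Extend a consensus while the copies' flanks still agree.

    Alignment-based recovery cannot pick up a residual element tail
    shorter than the alignability threshold, so — as a curator would —
    the per-copy flanks immediately beyond each terminus (already pinned
    per copy by `refine_flanks`) are stacked and the consensus grows base
    by base while a clear majority of copies agree; truly flanking DNA is
    copy-specific and stops the walk at once.
    """
    n = len(copies_with_flanks)
    if n < 3:
        return consensus

    def agreeing(seqs: list[str]) -> str:
        """Majority walk over stacked sequences, tolerating +-2 of
        per-copy junction offset: a naive column majority serves as the
        reference, each copy adopts the offset that best matches it, and
        the walk then runs on offset-adjusted columns."""
        ref = []
        for j in range(30):
            col = [s[j] for s in seqs if j < len(s) and s[j] in "ACGT"]
            if not col:
                break
            ref.append(Counter(col).most_common(1)[0][0])
        ref = "".join(ref)
        offsets = []
        for s in seqs:
            best, best_o = -1, 0
            for o in (-2, -1, 0, 1, 2):
                m = sum(1 for j in range(len(ref))
                        if 0 <= j + o < len(s) and s[j + o] == ref[j])
                if m > best:
                    best, best_o = m, o
            offsets.append(best_o)
        out = []
        for j in range(max_extension):
            chars = [s[j + o] for s, o in zip(seqs, offsets)
                     if 0 <= j + o < len(s) and s[j + o] in "ACGT"]
            if len(chars) < min_depth_frac * n:
                break
            base, cnt = Counter(chars).most_common(1)[0]
            if cnt < min_agree * len(chars):
                break
            out.append(base)
        return "".join(out)

    right_ext = agreeing([r for _, _, r in copies_with_flanks])
    left_ext = agreeing([left[::-1]
                         for left, _, _ in copies_with_flanks])[::-1]
    return left_ext + consensus + right_ext


def refine_flanks(consensus: str, copies, min_core_frac: float = 0.3,
                  anchor_k: int = 20) -> list[tuple[str, str, str]]:
    """Per-copy (left flank, element, right flank) by direct realignment.

    Flanks read off star-alignment columns inherit a few bp of per-copy
    wobble from the insertion-block merging; aligning the finished
    consensus back onto each raw copy pins each copy's element boundaries
    as tightly as the sequences allow, which is what hallmark detection
    (TSDs especially) needs. The global alignment's end placement is
    itself ambiguous by a base or two where terminal characters mismatch,
    so each junction is pinned by locally re-placing the consensus's
    terminal `anchor_k`-mer in a small window around it. Copies whose
    alignment covers too little of the consensus are dropped.
    """
    out = []
    k = min(anchor_k, len(consensus) // 2)
    for _, seq in copies:
        res = align(consensus, seq, mode="glocal")
        if res.a_end - res.a_start < min_core_frac * len(consensus):
            continue
        b_start, b_end = res.b_start, res.b_end
        if k >= 8:
            lo = max(0, b_start - 10)
            win = seq[lo:b_start + k + 10]
            if len(win) >= k:
                r = align(consensus[:k], win, mode="local")
                if r.matches >= 0.7 * k and r.a_start <= 2:
                    b_start = lo + r.b_start - r.a_start
            lo = max(0, b_end - k - 10)
            win = seq[lo:b_end + 10]
            if len(win) >= k:
                r = align(consensus[-k:], win, mode="local")
                if r.matches >= 0.7 * k and r.a_end >= k - 2:
                    b_end = lo + r.b_end + (k - r.a_end)
        if not 0 <= b_start < b_end <= len(seq):
            b_start, b_end = res.b_start, res.b_end
        out.append((seq[:b_start], seq[b_start:b_end], seq[b_end:]))
    return out
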