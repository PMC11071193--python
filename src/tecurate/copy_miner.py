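"""The "Blast-Extend" half of the curation loop.

Locate genomic copies of a draft consensus with the internal seed-and-extend
aligner (or an imported hit table), pick the best N hits, extend each by a
fixed flank on both sides (2 kb by default, the width curators use so that
element termini and target sites fall inside the alignment), and extract the
oriented sequences for alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from tecurate._dna import revcomp
from tecurate.align import find_local_hits
from tecurate.seqio import ConsensusRecord, HitRow

DEFAULT_TOP_N = 20
DEFAULT_FLANK = 2000


@dataclass
class Interval:
    """A located, stranded genomic span; 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    score: float = 0.0
    source_hit: HitRow | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.contig}:{self.start}-{self.end}")

    @property
    def label(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


_LABEL_RE = re.compile(r"^(.+):(\d+)-(\d+)\(([+-])\)$")


def parse_label(label: str) -> Interval:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unparseable interval label {label!r}")
    return Interval(contig=m.group(1), start=int(m.group(2)),
                    end=int(m.group(3)), strand=m.group(4))


def _as_contigs(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return dict(genome)


def find_copies(consensus: ConsensusRecord | str, genome, k: int = 11,
                min_score: int = 30, min_identity: float = 0.0,
                min_len: int = 0) -> list[HitRow]:
    """Locate genomic copies of a consensus on both strands.

    Hits are found by exact k-mer seeding, diagonal chaining and local
    affine-gap extension; minus-strand copies are found by searching the
    reverse complement. Rows are ordered by score desc, then contig and
    start. Returns an empty list (not an error) when nothing is found.
    """
    qname = consensus.id if isinstance(consensus, ConsensusRecord) else "query"
    qseq = consensus.sequence if isinstance(consensus, ConsensusRecord) else consensus
    if len(qseq) < k:
        raise ValueError(f"consensus {qname} shorter than seed length k={k}")
    L = len(qseq)
    rows: list[HitRow] = []
    for contig, seq in _as_contigs(genome).items():
        if len(seq) < k:
            continue
        for strand, query in (("+", qseq), ("-", revcomp(qseq))):
            for h in find_local_hits(query, seq, k=k, min_score=min_score):
                ident = 100.0 * h.identity
                if ident < min_identity or h.n_cols < min_len:
                    continue
                if strand == "+":
                    qs, qe = h.q_start + 1, h.q_end
                    ss, se = h.t_start + 1, h.t_end
                else:
                    qs, qe = L - h.q_end + 1, L - h.q_start
                    ss, se = h.t_end, h.t_start + 1  # sstart > send on minus
                rows.append(HitRow(
                    query=qname, subject=contig, identity=round(ident, 2),
                    aln_length=h.n_cols, mismatches=h.mismatches,
                    gap_opens=h.gap_opens, qstart=qs, qend=qe,
                    sstart=ss, send=se, evalue=0.0, bitscore=float(h.score),
                ))
    # deduplicate identical (contig, start, end, strand)
    uniq: dict[tuple, HitRow] = {}
    for r in rows:
        key = (r.subject, min(r.sstart, r.send), max(r.sstart, r.send), r.strand)
        if key not in uniq or r.bitscore > uniq[key].bitscore:
            uniq[key] = r
    return sorted(uniq.values(),
                  key=lambda r: (-r.bitscore, r.subject, min(r.sstart, r.send)))


def select_and_extend(hits: list[HitRow], n: int = DEFAULT_TOP_N,
                      flank: int = DEFAULT_FLANK,
                      contig_lengths: dict[str, int] | None = None) -> list[Interval]:
    """Top-n hits by bitscore, each extended by `flank` bp on both sides.

    Ties are broken by alignment length, then (contig, start) so selection
    is deterministic. Fragmented search output yields several overlapping
    hits on one genomic copy; hits whose span mostly overlaps a
    higher-scoring hit (by more than half of the shorter span) are culled
    so the top n are distinct loci — genuinely adjacent tandem copies
    overlap far less and are kept. Intervals are clipped to contig bounds
    and are NOT merged when they overlap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ranked = sorted(
        hits, key=lambda r: (-r.bitscore, -r.aln_length, r.subject,
                             min(r.sstart, r.send)))
    kept: list[HitRow] = []
    for r in ranked:
        lo, hi = min(r.sstart, r.send) - 1, max(r.sstart, r.send)
        dominated = False
        for k in kept:
            if k.subject != r.subject:
                continue
            klo, khi = min(k.sstart, k.send) - 1, max(k.sstart, k.send)
            overlap = min(hi, khi) - max(lo, klo)
            if overlap > 0.5 * min(hi - lo, khi - klo):
                dominated = True
                break
        if not dominated:
            kept.append(r)
    out = []
    for r in kept[:n]:
        lo = min(r.sstart, r.send) - 1  # to 0-based
        hi = max(r.sstart, r.send)
        start = max(0, lo - flank)
        end = hi + flank
        if contig_lengths is not None:
            end = min(end, contig_lengths[r.subject])
        out.append(Interval(contig=r.subject, start=start, end=end,
                            strand=r.strand, score=r.bitscore, source_hit=r))
    return out


def extract_oriented(genome, intervals: list[Interval]) -> list[tuple[str, str]]:
    """Extract interval sequences, reverse-complementing minus-strand ones.

    Every copy comes out in consensus orientation, labeled
    ``contig:start-end(strand)`` (parseable back via `parse_label`).
    """
    contigs = _as_contigs(genome)
    out = []
    for iv in intervals:
        if iv.contig not in contigs:
            raise ValueError(f"unknown contig {iv.contig!r}")
        seq = contigs[iv.contig]
        if iv.end > len(seq):
            raise ValueError(f"interval {iv.label} outside contig (len {len(seq)})")
        sub = seq[iv.start:iv.end]
        if iv.strand == "-":
            sub = revcomp(sub)
        out.append((iv.label, sub))
    return out
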