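"""Anchored star MSA construction and majority-rule IUPAC consensus calling.

This is the "Extract/curate" half of the curation loop. Extended genomic
copies are each aligned pairwise to the current consensus (the anchor) and
projected onto a shared coordinate system (a star alignment). The curated
consensus is then read off column by column under the majority rule:

* per column, the most representative IUPAC character (ambiguity codes for
  balanced columns, ``N`` when nothing qualifies);
* per indel region, each insertion/deletion length is treated as an
  independent event and the plurality length wins (ties toward the shorter,
  deletion-favoring variant);
* regions too complex to resolve receive a fixed ``NNNNNNNNNN`` placeholder
  (10 Ns regardless of region width);
* the element termini are found by scanning inward for the first window
  where the alignment is deep and consistent (the "alignable part");
  flanking sequence outside it is retained per copy for hallmark detection.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tecurate._dna import iupac_code
from tecurate.align import align
from tecurate.seqio import ConsensusRecord

GAP = "-"
PLACEHOLDER = "N" * 10

# consensus-rule defaults; the majority rule itself is the method, the
# numeric thresholds are configurable curator knobs
DEFAULT_MAJORITY_FRAC = 0.5
DEFAULT_MINOR_FRAC = 0.25
DEFAULT_MIN_DEPTH = 3
DEFAULT_DEPTH_FRAC = 0.5
DEFAULT_AGREEMENT_MIN = 0.7
DEFAULT_WINDOW = 15
DEFAULT_COMPLEXITY_FRAC = 1.0 / 3.0
DEFAULT_MAX_LENGTH_CLASSES = 4

# columns are treated as part of one indel event when at least this fraction
# of spanning rows gap there; sparser gaps are handled by the column rule
DEFAULT_GAP_REGION_FRAC = 0.25

# insertion blocks wider than this are merged by a mini star alignment
# anchored on the longest inserted segment instead of naive justification
MERGE_THRESHOLD = 24

# anchored-extension alignments below this score are junk (random flank
# pairs chance-match a handful of bases at the junction, which would
# otherwise fabricate conserved-looking columns); such segments are kept
# unaligned, away from the junction
MIN_EXTEND_SCORE = 18


@dataclass
class MSA:
    """Anchored multiple alignment: uniform-length gapped rows."""

    rows: list[tuple[str, str]]
    anchor_index: int = 0

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if not 0 <= self.anchor_index < len(self.rows):
            raise ValueError("anchor row missing")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """Rows as a 2D array of single characters."""
        return np.array([list(s) for _, s in self.rows], dtype="<U1")

    def spans(self) -> list[tuple[int, int]]:
        """Per row, (first, last+1) non-gap column; (0, 0) for all-gap rows."""
        out = []
        for _, s in self.rows:
            stripped = s.strip(GAP)
            if not stripped:
                out.append((0, 0))
                continue
            first = len(s) - len(s.lstrip(GAP))
            out.append((first, first + len(stripped)))
        return out


@dataclass
class ColumnProfile:
    """Character counts at one alignment column."""

    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def depth(self) -> int:
        return sum(n for c, n in self.counts.items() if c != GAP)


# ------------------------------------------------------------ star alignment

def _project(anchor: str, copy: str, mode: str,
             extend_min_score: int = MIN_EXTEND_SCORE):
    """Align one copy to the anchor and express it in anchor coordinates.

    Returns (cols, inserts): `cols[i]` is the copy character (or gap) at
    anchor position i; `inserts[s]` is copy sequence falling between anchor
    positions s-1 and s (s=0 before the anchor, s=len(anchor) after it).
    """
    res = align(anchor, copy, mode=mode)
    n = len(anchor)
    cols = [GAP] * n
    if mode == "extend" and res.score < extend_min_score:
        return cols, {n: copy}
    inserts: dict[int, list[str]] = {}
    if res.b_start > 0:
        inserts.setdefault(res.a_start, []).append(copy[:res.b_start])
    i, j = res.a_start, res.b_start
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if ca != GAP and cb != GAP:
            cols[i] = copy[j]
            i += 1
            j += 1
        elif cb == GAP:
            i += 1
        else:
            inserts.setdefault(i, []).append(copy[j])
            j += 1
    if res.b_end < len(copy):
        inserts.setdefault(res.a_end, []).append(copy[res.b_end:])
    return cols, {s: "".join(parts) for s, parts in inserts.items()}


def _mini_star_block(segs: dict[int, str], side: str) -> dict[int, str]:
    """Merge one wide insertion block by star-aligning its segments.

    Boundary blocks share a junction with the main anchor — leading blocks
    (`side`="start") end at it, trailing blocks ("end") begin at it — so
    their segments are aligned by anchored extension from that junction,
    which keeps shared element sequence in register right up to the
    junction instead of letting a local alignment trim ragged ends.
    Interior blocks fall back to local alignment. The segment of median
    length anchors the merge: boundary segments are typically flank-width
    plus any shared element sequence, and the median avoids aberrant
    segments from partial or secondary hits.
    """
    by_len = sorted(segs, key=lambda i: len(segs[i]))
    anchor_idx = by_len[len(by_len) // 2]
    rev = side == "start"
    flip = (lambda s: s[::-1]) if rev else (lambda s: s)
    anchor_seq = flip(segs[anchor_idx])
    others = [(i, flip(s)) for i, s in segs.items() if i != anchor_idx]
    mode = "extend" if side in ("start", "end") else "local"
    anchor_gapped, rows = _star(anchor_seq, [s for _, s in others],
                                merge_big_blocks=False, mode=mode)
    out = {anchor_idx: flip(anchor_gapped)}
    for (i, _), row in zip(others, rows):
        out[i] = flip(row)
    return out


def _star(anchor_seq: str, copies: Sequence[str], merge_big_blocks: bool = True,
          mode: str = "glocal",
          extend_min_score: int = MIN_EXTEND_SCORE) -> tuple[str, list[str]]:
    projections = [_project(anchor_seq, c, mode, extend_min_score)
                   for c in copies]
    n = len(anchor_seq)
    widths = [0] * (n + 1)
    for _, ins in projections:
        for s, txt in ins.items():
            widths[s] = max(widths[s], len(txt))
    blocks: dict[int, tuple[int, dict[int, str]]] = {}
    for s in range(n + 1):
        w = widths[s]
        if w == 0:
            continue
        segs = {idx: ins.get(s, "") for idx, (_, ins) in enumerate(projections)
                if ins.get(s)}
        if merge_big_blocks and w > MERGE_THRESHOLD and len(segs) > 1:
            side = "start" if s == 0 else ("end" if s == n else "interior")
            sub = _mini_star_block(segs, side)
            w = len(next(iter(sub.values())))
        else:
            just = str.rjust if s == 0 else str.ljust
            sub = {idx: just(t, w, GAP) for idx, t in segs.items()}
        blocks[s] = (w, sub)
    anchor_parts: list[str] = []
    row_parts: list[list[str]] = [[] for _ in copies]
    for s in range(n + 1):
        if s in blocks:
            w, sub = blocks[s]
            anchor_parts.append(GAP * w)
            for idx in range(len(copies)):
                row_parts[idx].append(sub.get(idx, GAP * w))
        if s < n:
            anchor_parts.append(anchor_seq[s])
            for idx, (cols, _) in enumerate(projections):
                row_parts[idx].append(cols[s])
    return "".join(anchor_parts), ["".join(p) for p in row_parts]


def build_star_msa(anchor: ConsensusRecord | tuple[str, str],
                   copies: Sequence[tuple[str, str]]) -> MSA:
    """Anchored star alignment of extended copies on the current consensus.

    Each copy is aligned pairwise to the anchor (global with cost-free end
    gaps, affine penalties) and the alignments are projected onto shared
    anchor columns; copy-only residues become anchor-gap columns. Wide
    insertion blocks (leading/trailing flanks, sequence absent from a
    truncated anchor) are themselves merged by a mini star alignment so that
    sequence shared between copies beyond the anchor stays in register.
    """
    if not copies:
        raise ValueError("no copies to align")
    if isinstance(anchor, ConsensusRecord):
        label, seq = f"{anchor.id}.v{anchor.version}", anchor.sequence
    else:
        label, seq = anchor
    anchor_gapped, rows = _star(seq, [c for _, c in copies])
    all_rows = [(label, anchor_gapped)] + [
        (lab, row) for (lab, _), row in zip(copies, rows)]
    return MSA(rows=all_rows, anchor_index=0)


# ------------------------------------------------------------ consensus rules

def column_consensus(profile: ColumnProfile | Mapping[str, int],
                     majority_frac: float = DEFAULT_MAJORITY_FRAC,
                     minor_frac: float = DEFAULT_MINOR_FRAC) -> str:
    """Majority-rule IUPAC call for one column.

    Gap wins when more than half of all rows gap; otherwise the top base
    wins when its frequency among non-gap rows strictly exceeds
    `majority_frac`; otherwise the ambiguity code of all bases at frequency
    >= `minor_frac`; ``N`` when no base qualifies.
    """
    counts = profile.counts if isinstance(profile, ColumnProfile) else profile
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty column profile")
    gaps = counts.get(GAP, 0)
    if gaps > 0.5 * total:
        return GAP
    depth = total - gaps
    if depth == 0:
        return GAP
    base_counts = {b: counts.get(b, 0) for b in "ACGT"}
    top = max(base_counts.values())
    if top > majority_frac * depth:
        return max(base_counts, key=base_counts.get)
    qualified = {b for b, c in base_counts.items() if c >= minor_frac * depth and c > 0}
    if not qualified:
        return "N"
    return iupac_code(qualified)


@dataclass
class IndelResolution:
    """Outcome of the independent-event majority rule on one gap region."""

    kept_length: int
    sequence: str
    is_placeholder: bool = False
    length_classes: dict[int, int] = field(default_factory=dict)


def _region_rows(msa: MSA, region: tuple[int, int], include_anchor: bool = False):
    """Rows whose aligned span fully covers the region (end gaps excluded)."""
    c0, c1 = region
    spans = msa.spans()
    idxs = []
    for i, (s0, s1) in enumerate(spans):
        if i == msa.anchor_index and not include_anchor:
            continue
        if s0 <= c0 and s1 >= c1:
            idxs.append(i)
    return idxs


def unresolved_placeholder(msa: MSA, region: tuple[int, int],
                           complexity_frac: float = DEFAULT_COMPLEXITY_FRAC,
                           max_length_classes: int = DEFAULT_MAX_LENGTH_CLASSES) -> str | None:
    """10-N placeholder if the region is too complex to resolve, else None.

    A region is complex when its rows fall into more than
    `max_length_classes` distinct indel-length classes, or when no class
    reaches `complexity_frac` of the informative rows.
    """
    c0, c1 = region
    idxs = _region_rows(msa, region)
    if not idxs:
        return None
    classes = Counter(
        sum(1 for ch in msa.rows[i][1][c0:c1] if ch != GAP) for i in idxs)
    if len(classes) > max_length_classes:
        return PLACEHOLDER
    if max(classes.values()) < complexity_frac * len(idxs):
        return PLACEHOLDER
    return None


def indel_consensus(msa: MSA, region: tuple[int, int],
                    majority_frac: float = DEFAULT_MAJORITY_FRAC,
                    minor_frac: float = DEFAULT_MINOR_FRAC,
                    complexity_frac: float = DEFAULT_COMPLEXITY_FRAC,
                    max_length_classes: int = DEFAULT_MAX_LENGTH_CLASSES) -> IndelResolution:
    """Resolve one gap region treating each indel length as one event.

    Rows are grouped by how many residues they place in the region; the
    plurality length class wins (ties toward the shorter, i.e. the
    deletion-favoring variant) and the kept columns are filled by the
    column rule over the winning rows. Complex regions get the 10-N
    placeholder.
    """
    c0, c1 = region
    idxs = _region_rows(msa, region)
    if not idxs:
        return IndelResolution(kept_length=0, sequence="")
    residues = {i: [ch for ch in msa.rows[i][1][c0:c1] if ch != GAP] for i in idxs}
    classes = Counter(len(r) for r in residues.values())
    ph = unresolved_placeholder(msa, region, complexity_frac, max_length_classes)
    if ph is not None:
        return IndelResolution(kept_length=len(ph), sequence=ph,
                               is_placeholder=True, length_classes=dict(classes))
    best = max(classes.values())
    kept = min(length for length, cnt in classes.items() if cnt == best)
    if kept == 0:
        return IndelResolution(kept_length=0, sequence="", length_classes=dict(classes))
    winners = [residues[i] for i in idxs if len(residues[i]) == kept]
    out = []
    for p in range(kept):
        counts = Counter(r[p] for r in winners)
        out.append(column_consensus(counts, majority_frac, minor_frac))
    return IndelResolution(kept_length=kept, sequence="".join(out),
                           length_classes=dict(classes))


# ------------------------------------------------------------ termini

def _column_stats(msa: MSA):
    mat = msa.matrix()
    depth = (mat != GAP).sum(axis=0)
    base_max = np.zeros(msa.ncols, dtype=int)
    for b in "ACGT":
        base_max = np.maximum(base_max, (mat == b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        agree = np.where(depth > 0, base_max / np.maximum(depth, 1), 0.0)
    return depth, agree


def detect_termini(msa: MSA, window: int = DEFAULT_WINDOW,
                   min_depth: int = DEFAULT_MIN_DEPTH,
                   depth_frac: float = DEFAULT_DEPTH_FRAC,
                   agreement_min: float = DEFAULT_AGREEMENT_MIN) -> tuple[int, int]:
    """Locate the alignable part (the element proper) among flanking DNA.

    Scans a sliding window inward from each end; the alignable part starts
    at the first window whose mean depth and mean top-base agreement pass
    the thresholds, refined to the first qualifying column inside that
    window. Depth must reach both the absolute `min_depth` floor and
    `depth_frac` of the copies — the alignable part is where most copies
    align, which keeps pockets of coincidentally shared or stacked flank
    sequence out of the element. Returns a half-open column range.
    """
    depth, agree = _column_stats(msa)
    min_depth = max(min_depth, depth_frac * max(msa.nrows - 1, 1))
    # a near-empty column is trivially self-consistent; its agreement must
    # not prop up a window's mean
    masked_agree = np.where(depth >= DEFAULT_MIN_DEPTH, agree, 0.0)
    L = msa.ncols
    w = min(window, L)
    if w == 0:
        raise ValueError("no alignable core (empty alignment)")
    kernel = np.ones(w) / w
    mean_depth = np.convolve(depth, kernel, mode="valid")
    mean_agree = np.convolve(masked_agree, kernel, mode="valid")
    ok = (mean_depth >= min_depth) & (mean_agree >= agreement_min)
    if not ok.any():
        raise ValueError("no alignable core")
    s_win = int(np.argmax(ok))
    e_win = int(len(ok) - 1 - np.argmax(ok[::-1]))
    # refine to the outermost strictly-qualifying column; a window can
    # qualify on its mean alone, so the scan continues inward past it
    # rather than defaulting to the window edge
    strict = (depth >= min_depth) & (agree >= agreement_min)
    start = end = None
    for j in range(s_win, L):
        if strict[j]:
            start = j
            break
    for j in range(e_win + w - 1, -1, -1):
        if strict[j]:
            end = j + 1
            break
    if start is None or end is None or start >= end:
        raise ValueError("no alignable core")
    # the strict thresholds shave a few columns off a ragged element edge
    # where not every copy's alignment reaches; walk outward accepting
    # columns that are either still deep and consistent, or shallow but
    # near-unanimous (the taper of a true edge — random stacked flanks are
    # rarely unanimous), tolerating up to two ragged columns in a row
    relax_depth = max(DEFAULT_MIN_DEPTH, 0.8 * min_depth)
    relax_agree = 0.8 * agreement_min

    def _qual(j):
        if depth[j] >= relax_depth and agree[j] >= relax_agree:
            return True
        return depth[j] >= DEFAULT_MIN_DEPTH and agree[j] >= 0.9

    miss = 0
    j = start - 1
    while j >= 0 and miss <= 2:
        if _qual(j):
            start = j
            miss = 0
        else:
            miss += 1
        j -= 1
    miss = 0
    j = end
    while j < L and miss <= 2:
        if _qual(j):
            end = j + 1
            miss = 0
        else:
            miss += 1
        j += 1
    return start, end


# ------------------------------------------------------------ assembly

def consensus_from_msa(msa: MSA, start: int, end: int,
                       majority_frac: float = DEFAULT_MAJORITY_FRAC,
                       minor_frac: float = DEFAULT_MINOR_FRAC,
                       complexity_frac: float = DEFAULT_COMPLEXITY_FRAC,
                       max_length_classes: int = DEFAULT_MAX_LENGTH_CLASSES,
                       gap_region_frac: float = DEFAULT_GAP_REGION_FRAC
                       ) -> tuple[str, str]:
    """Consensus over columns [start, end); returns (sequence, gapped row).

    Columns where at least `gap_region_frac` of spanning rows gap are
    grouped into maximal indel regions and resolved by `indel_consensus`;
    the remaining columns go through `column_consensus`. The gapped row
    places the consensus back in MSA coordinates for version snapshots.
    """
    mat = msa.matrix()
    spans = msa.spans()
    nrow, L = mat.shape
    copy_idx = [i for i in range(nrow) if i != msa.anchor_index]
    in_span = np.zeros((nrow, L), dtype=bool)
    for i, (s0, s1) in enumerate(spans):
        in_span[i, s0:s1] = True
    is_gap = (mat == GAP) & in_span
    span_depth = in_span[copy_idx].sum(axis=0)
    gap_count = is_gap[copy_idx].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gap_frac = np.where(span_depth > 0, gap_count / np.maximum(span_depth, 1), 0.0)
    region_col = gap_frac >= gap_region_frac

    out: list[str] = []
    gapped = [GAP] * L
    j = start
    while j < end:
        if region_col[j]:
            j2 = j
            while j2 < end and region_col[j2]:
                j2 += 1
            res = indel_consensus(msa, (j, j2), majority_frac, minor_frac,
                                  complexity_frac, max_length_classes)
            out.append(res.sequence)
            for p, ch in enumerate(res.sequence[:j2 - j]):
                gapped[j + p] = ch
            j = j2
        else:
            counts = Counter(
                mat[i, j] for i in copy_idx if in_span[i, j])
            if not counts:
                j += 1
                continue
            ch = column_consensus(counts, majority_frac, minor_frac)
            if ch != GAP:
                out.append(ch)
                gapped[j] = ch
            j += 1
    return "".join(out), "".join(gapped)


@dataclass
class CurationResult:
    """Everything one curation pass produces."""

    record: ConsensusRecord
    msa: MSA
    core_cols: tuple[int, int]
    copies_with_flanks: list[tuple[str, str, str, str]]  # label, left, core, right


def curate(anchor: ConsensusRecord, copies: Sequence[tuple[str, str]],
           curator: str | None = None, window: int = DEFAULT_WINDOW,
           min_depth: int = DEFAULT_MIN_DEPTH,
           agreement_min: float = DEFAULT_AGREEMENT_MIN,
           majority_frac: float = DEFAULT_MAJORITY_FRAC,
           minor_frac: float = DEFAULT_MINOR_FRAC,
           complexity_frac: float = DEFAULT_COMPLEXITY_FRAC,
           max_length_classes: int = DEFAULT_MAX_LENGTH_CLASSES) -> CurationResult:
    """One curation pass: star MSA, termini, majority-rule consensus.

    Produces the next version of the consensus (status ``curated``) and
    appends its gapped projection to the alignment so all versions stay in
    the same file. Per-copy flanks outside the alignable part are returned
    for hallmark detection.
    """
    msa = build_star_msa(anchor, copies)
    start, end = detect_termini(msa, window=window, min_depth=min_depth,
                                agreement_min=agreement_min)
    seq, gapped = consensus_from_msa(
        msa, start, end, majority_frac=majority_frac, minor_frac=minor_frac,
        complexity_frac=complexity_frac, max_length_classes=max_length_classes)
    if not seq:
        raise ValueError("curation produced an empty consensus")
    record = ConsensusRecord(
        id=anchor.id, classification=anchor.classification, sequence=seq,
        version=anchor.version + 1, status="curated", curator=curator)
    versioned = MSA(
        rows=msa.rows + [(f"{record.id}.v{record.version}", gapped)],
        anchor_index=msa.anchor_index)
    flanks = []
    for i, (label, row) in enumerate(msa.rows):
        if i == msa.anchor_index:
            continue
        left = row[:start].replace(GAP, "")
        core = row[start:end].replace(GAP, "")
        right = row[end:].replace(GAP, "")
        flanks.append((label, left, core, right))
    return CurationResult(record=record, msa=versioned,
                          core_cols=(start, end), copies_with_flanks=flanks)


def length_comparison(before: Sequence[ConsensusRecord],
                      after: Sequence[ConsensusRecord]):
    """Per-record length change across curation plus a summary.

    Records are matched by id; unmatched ids are reported and excluded.
    Returns (table, summary) where summary carries the median delta.
    """
    b = {r.id: len(r) for r in before}
    a = {r.id: len(r) for r in after}
    shared = sorted(b.keys() & a.keys())
    unmatched = sorted(b.keys() ^ a.keys())
    if unmatched:
        warnings.warn(f"{len(unmatched)} unmatched record id(s) excluded: "
                      f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}")
    table = pd.DataFrame({
        "id": shared,
        "len_before": [b[i] for i in shared],
        "len_after": [a[i] for i in shared],
    })
    table["delta"] = table["len_after"] - table["len_before"]
    summary = {
        "n": len(shared),
        "median_delta": float(table["delta"].median()) if shared else float("nan"),
        "unmatched": unmatched,
    }
    return table, summary
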