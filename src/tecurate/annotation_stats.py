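"""Annotation-derived statistics: Kimura 2-parameter divergence, repeat
landscapes, per-category masked fractions and the activity filter.

A repeat landscape bins the masked base pairs of a genome by the divergence
of each copy from its consensus (Kimura 2-parameter distance, which corrects
separately for transitions and transversions) and reads as a relative age
profile: mass near 0% divergence means recent activity. The activity filter
flags subfamilies with at least `min_copies` annotated copies at (close to)
0% divergence as putatively still mobile.

Divergence defaults to the ``pct_div`` column of the ``.out`` table (what
the masking tool chain's own scripts consume); recomputation from alignment
rows via `divergence_from_pair` is available when alignments are at hand.
No CpG adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from tecurate.seqio import AnnotationRow

LANDSCAPE_MAX_DIV = 50.0  # rows at >= 49 pool into the last bin

MAIN_CATEGORIES = ["DNA", "LINE", "SINE", "LTR", "Unknown"]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DivergenceEstimate:
    p: float  # transition proportion
    q: float  # transversion proportion
    k: float  # Kimura 2-parameter distance
    n_sites: int = 0


def kimura2p(p: float, q: float) -> float:
    """Kimura 2-parameter distance K = -1/2 ln(1-2p-q) - 1/4 ln(1-2q)."""
    if p < 0 or q < 0:
        raise ValueError("p and q must be non-negative")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise ValueError("saturated divergence: K2P distance undefined")
    return -0.5 * math.log(a) - 0.25 * math.log(b)


def divergence_from_pair(consensus_row: str, copy_row: str) -> DivergenceEstimate:
    """K2P estimate from two equal-length gapped alignment rows.

    Transitions are A<->G and C<->T; columns with a gap or an ambiguous
    base in either row are excluded from the denominator.
    """
    if len(consensus_row) != len(copy_row):
        raise ValueError("alignment rows differ in length")
    n = ts = tv = 0
    for a, b in zip(consensus_row.upper(), copy_row.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    p, q = ts / n, tv / n
    return DivergenceEstimate(p=p, q=q, k=kimura2p(p, q), n_sites=n)


@dataclass
class LandscapeMatrix:
    """Masked bp per (top-level category, divergence bin)."""

    table: pd.DataFrame  # index: category, columns: bin left edges
    genome_size: int
    bin_width: float

    def percent(self) -> pd.DataFrame:
        return self.table / self.genome_size * 100.0

    @property
    def total_bp(self) -> int:
        return int(self.table.to_numpy().sum())


def landscape(rows: Sequence[AnnotationRow], genome_size: int,
              bin_width: float = 1.0,
              divergence_source: str = "pct_div") -> LandscapeMatrix:
    """Repeat landscape: masked bp binned by divergence and category.

    Each row contributes its full masked span to the half-open bin
    [k*w, (k+1)*w) of its divergence; rows at >= 49% pool into the last
    bin. Overlaps are NOT flattened (standard landscape semantics), so the
    cell total equals the summed row lengths.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if divergence_source != "pct_div":
        raise ValueError("only pct_div divergence is supported here; "
                         "use divergence_from_pair for alignment rows")
    edges = np.arange(0.0, LANDSCAPE_MAX_DIV, bin_width)
    cats = sorted({r.category for r in rows} | set(MAIN_CATEGORIES))
    table = pd.DataFrame(0, index=cats, columns=edges, dtype=int)
    for r in rows:
        if r.pct_div < 0:
            raise ValueError(f"negative divergence on {r.query}:{r.qbegin}")
        div = min(r.pct_div, LANDSCAPE_MAX_DIV - bin_width)
        b = edges[min(int(div // bin_width), len(edges) - 1)]
        table.loc[r.category, b] += r.span
    return LandscapeMatrix(table=table, genome_size=genome_size,
                           bin_width=bin_width)


def masked_summary(rows: Sequence[AnnotationRow], genome_size: int,
                   resolve_overlaps: bool = True) -> pd.DataFrame:
    """Masked bp and percent of genome per main category, plus the total.

    With `resolve_overlaps`, overlapping annotations are flattened so each
    base counts once, attributed to the highest-scoring row covering it;
    the summed percentage then cannot exceed 100.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    bp: dict[str, int] = {c: 0 for c in MAIN_CATEGORIES}
    if resolve_overlaps:
        claimed: dict[str, IntervalTree] = {}
        for r in sorted(rows, key=lambda r: -r.score):
            tree = claimed.setdefault(r.query, IntervalTree())
            lo, hi = r.qbegin - 1, r.qend  # to 0-based half-open
            free = [(lo, hi)]
            for iv in sorted(tree.overlap(lo, hi)):
                nxt = []
                for s, e in free:
                    if iv.end <= s or iv.begin >= e:
                        nxt.append((s, e))
                        continue
                    if s < iv.begin:
                        nxt.append((s, iv.begin))
                    if iv.end < e:
                        nxt.append((iv.end, e))
                free = nxt
            gained = sum(e - s for s, e in free)
            if gained:
                cat = r.category if r.category in bp else "Unknown"
                bp[cat] = bp.get(cat, 0) + gained
                for s, e in free:
                    tree.addi(s, e)
    else:
        for r in rows:
            cat = r.category if r.category in bp else "Unknown"
            bp[cat] = bp.get(cat, 0) + r.span
    out = pd.DataFrame({
        "bp": [bp[c] for c in MAIN_CATEGORIES],
        "percent": [bp[c] / genome_size * 100.0 for c in MAIN_CATEGORIES],
    }, index=MAIN_CATEGORIES)
    out.loc["total"] = [out["bp"].sum(), out["percent"].sum()]
    return out


def active_subfamilies(rows: Iterable[AnnotationRow], min_copies: int = 10,
                       max_div: float = 0.0) -> pd.DataFrame:
    """Putatively active subfamilies per category.

    A subfamily (unique repeat name) qualifies when at least `min_copies`
    of its annotated copies show divergence <= `max_div` (default: exactly
    0% distance to consensus). Returns per-category counts with the
    qualifying names.
    """
    per_name: dict[str, int] = {}
    name_cat: dict[str, str] = {}
    for r in rows:
        name_cat[r.repeat_name] = r.category
        if r.pct_div <= max_div:
            per_name[r.repeat_name] = per_name.get(r.repeat_name, 0) + 1
    qualifying = sorted(n for n, c in per_name.items() if c >= min_copies)
    cats = sorted({name_cat[n] for n in qualifying})
    return pd.DataFrame({
        "n_subfamilies": [sum(1 for n in qualifying if name_cat[n] == c)
                          for c in cats],
        "subfamilies": [",".join(n for n in qualifying if name_cat[n] == c)
                        for c in cats],
    }, index=cats)
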