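"""Classification and nomenclature: RepeatMasker-style labels, homology and
structure rules, library comparison under the 80-80-80 / 95-80-98 rules.

Classification labels follow the ``Class/Superfamily`` convention required
by the masking tool chain; misspelled labels (``DNA/Hat``, ``LTR/Gipsy``)
break downstream scripts silently, so the vocabulary validator suggests the
nearest valid token. Library comparison decides whether two consensus
sequences represent the same family (80-80-80: >=80 bp aligned, >=80%
identity, covering >=80% of the shorter sequence) or the same subfamily
(95-80-98 preset, interpreted by analogy as identity >=95%, coverage >=80%,
span >=98 bp; overridable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from tecurate.align import find_local_hits
from tecurate.seqio import ConsensusRecord, LedgerEntry

DEFAULT_CLASSES = {
    "DNA": ["CMC", "MULE", "TcMar", "Sola", "PiggyBac", "PIF-Harbinger",
            "Zator", "hAT", "Maverick", "P", "Zisupton"],
    "LINE": ["L1", "I", "CR1", "CRE", "R2", "R2-NesL", "L2", "RTE-X",
             "RTE-BovB"],
    "SINE": [],
    "LTR": ["DIRS", "Gypsy", "Ngaro", "Pao"],
    "RC": ["Helitron"],
    "Unknown": [],
    "Satellite": [],
    "Simple_repeat": [],
    "Low_complexity": [],
}

RULE_PRESETS = {
    # (min identity %, min coverage of the shorter seq, min aligned span bp)
    "80-80-80": (80.0, 0.80, 80),
    "95-80-98": (95.0, 0.80, 98),
}


@dataclass
class NomenclatureVocabulary:
    """Allowed classes and per-class superfamily tokens (case-sensitive)."""

    classes: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASSES.items()})

    def all_labels(self) -> list[str]:
        out = []
        for cls, sups in self.classes.items():
            out.append(cls)
            out.extend(f"{cls}/{sup}" for sup in sups)
        return out


@dataclass
class NameIssue:
    message: str
    suggestion: str | None = None


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def validate_name(label: str, vocabulary: NomenclatureVocabulary | None = None,
                  max_suggest_distance: int = 2) -> list[NameIssue]:
    """Check a ``Class/Superfamily`` label; empty list means valid.

    Superfamily tokens may carry a ``-FamilyName`` suffix (e.g.
    ``DNA/TcMar-Tc4``); the part before the dash must be a known token.
    Suggestions are the nearest valid token within edit distance 2.
    """
    vocab = vocabulary or NomenclatureVocabulary()
    issues: list[NameIssue] = []

    def nearest(token: str, candidates) -> str | None:
        # wrong capitalisation is the most common nomenclature mistake
        for c in candidates:
            if token.lower() == c.lower():
                return c
        scored = sorted(((_edit_distance(token, c), c) for c in candidates))
        if scored and scored[0][0] <= max_suggest_distance:
            return scored[0][1]
        return None

    if "/" in label:
        cls, sup = label.split("/", 1)
    else:
        cls, sup = label, None
    if cls not in vocab.classes:
        sug = nearest(cls, vocab.classes.keys())
        issues.append(NameIssue(f"unknown class {cls!r}",
                                suggestion=sug and (f"{sug}/{sup}" if sup else sug)))
        return issues
    if sup is not None:
        allowed = vocab.classes[cls]
        base = sup.split("-", 1)[0]
        if sup not in allowed and base not in allowed:
            sug = nearest(base, allowed)
            issues.append(NameIssue(
                f"unknown superfamily {sup!r} for class {cls}",
                suggestion=sug and f"{cls}/{sug}"))
    return issues


# ------------------------------------------------------------- classify

@dataclass
class HomologyHit:
    subject: str
    subject_classification: str
    identity: float        # percent
    coverage: float        # of the consensus, in [0, 1]
    evalue: float

    def __post_init__(self):
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must be in [0, 1]")


@dataclass
class Classification:
    label: str
    tier: str               # homology | structure | none
    trace: list[str]


def classify(record: ConsensusRecord, hallmarks=None,
             homology: list[HomologyHit] | None = None,
             max_evalue: float = 1e-5, min_coverage: float = 0.5) -> Classification:
    """Rule-based classification with a full decision trace.

    Precedence: (1) homology — the best qualifying subject's classification
    is adopted; (2) structure — TIR+TSD implies a DNA transposon, an LTR
    pair an LTR retrotransposon, conservatively without a superfamily;
    (3) otherwise Unknown. A structure/homology conflict is noted in the
    trace; homology wins.
    """
    trace: list[str] = []
    structural = None
    if hallmarks is not None:
        has_tsd = hallmarks.tsd is not None and hallmarks.tsd.consensus_length > 0
        if hallmarks.tir is not None and has_tsd:
            structural = "DNA/Unknown"
            trace.append(f"structure: TIR arms {hallmarks.tir.five}/"
                         f"{hallmarks.tir.three} + TSD len "
                         f"{hallmarks.tsd.consensus_length} -> DNA/Unknown")
        elif hallmarks.ltr is not None:
            structural = "LTR/Unknown"
            trace.append(f"structure: LTR pair len {hallmarks.ltr.length} "
                         f"identity {hallmarks.ltr.identity:.2f} -> LTR/Unknown")
        else:
            trace.append("structure: no TIR+TSD, no LTR pair")
    qualifying = [h for h in (homology or [])
                  if h.evalue <= max_evalue and h.coverage >= min_coverage]
    if qualifying:
        best = min(qualifying, key=lambda h: (h.evalue, -h.coverage, -h.identity))
        trace.append(f"homology: {best.subject} ({best.subject_classification}) "
                     f"e={best.evalue:g} cov={best.coverage:.2f} -> adopt")
        if structural is not None:
            s_cls = structural.split("/")[0]
            h_cls = best.subject_classification.split("/")[0]
            if s_cls != h_cls:
                trace.append(f"conflict: structure suggests {s_cls}, homology "
                             f"says {h_cls}; homology wins")
        return Classification(best.subject_classification, "homology", trace)
    if homology is not None and homology:
        trace.append("homology: no hit passes e-value/coverage thresholds")
    if structural is not None:
        return Classification(structural, "structure", trace)
    trace.append("no evidence -> Unknown")
    return Classification("Unknown", "none", trace)


# ------------------------------------------------------------- library compare

@dataclass
class LibraryPair:
    a_id: str
    b_id: str
    identity: float      # percent, span-weighted over kept fragments
    coverage: float      # of the shorter sequence
    span: int            # aligned bp summed over kept fragments


def _pair_stats(a: str, b: str, k: int = 11) -> tuple[float, float, int]:
    """(identity %, coverage of shorter, summed span) for one sequence pair.

    Fragmented local alignments are summed: hits are kept greedily by score
    while non-overlapping on the shorter sequence, identity is span-weighted
    (best-identity fragments dominate), and coverage is the union of kept
    fragments over the shorter length.
    """
    query, target = (b, a) if len(b) <= len(a) else (a, b)
    try:
        hits = find_local_hits(query, target, k=k)
    except ValueError:
        return 0.0, 0.0, 0
    kept = []
    covered: list[tuple[int, int]] = []
    for h in hits:  # already score-descending
        if any(h.q_start < e and s < h.q_end for s, e in covered):
            continue
        kept.append(h)
        covered.append((h.q_start, h.q_end))
    if not kept:
        return 0.0, 0.0, 0
    span = sum(h.n_cols for h in kept)
    ident = 100.0 * sum(h.matches for h in kept) / span
    cov = sum(e - s for s, e in covered) / len(query)
    return ident, cov, span


def compare_libraries(lib_a, lib_b, rule="80-80-80"):
    """Pair library sequences under a family/subfamily similarity rule.

    `rule` is a preset name or an explicit (min_identity_percent,
    min_coverage, min_span_bp) triple. Returns (pairs, orphans_a,
    orphans_b) where orphans have no qualifying partner.
    """
    if isinstance(rule, str):
        if rule not in RULE_PRESETS:
            raise ValueError(f"unknown rule preset {rule!r}")
        min_ident, min_cov, min_span = RULE_PRESETS[rule]
    else:
        min_ident, min_cov, min_span = rule
    if not lib_a or not lib_b:
        raise ValueError("both libraries must be non-empty")
    pairs = []
    matched_a, matched_b = set(), set()
    for ra in lib_a:
        for rb in lib_b:
            ident, cov, span = _pair_stats(ra.sequence, rb.sequence)
            if span >= min_span and ident >= min_ident and cov >= min_cov:
                pairs.append(LibraryPair(a_id=ra.id, b_id=rb.id,
                                         identity=round(ident, 2),
                                         coverage=round(cov, 4), span=span))
                matched_a.add(ra.id)
                matched_b.add(rb.id)
    orphans_a = [r.id for r in lib_a if r.id not in matched_a]
    orphans_b = [r.id for r in lib_b if r.id not in matched_b]
    return pairs, orphans_a, orphans_b


# ------------------------------------------------------------- renaming

def rename_library(lib: list[ConsensusRecord], prefix: str,
                   curator: str = "", timestamp: str = ""):
    """Prefix every record id (``prefix_origName``), emitting ledger entries.

    Mirrors replacing the automated ``rnd`` prefixes with species
    abbreviations (e.g. ``hypDuj``, ``ramVar``).
    """
    import re
    if not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", prefix):
        raise ValueError(f"invalid prefix {prefix!r}")
    new_names = [f"{prefix}_{r.id}" for r in lib]
    if len(set(new_names)) != len(new_names):
        dupes = sorted({n for n in new_names if new_names.count(n) > 1})
        raise ValueError(f"name collision after rename: {dupes}")
    renamed = []
    entries = []
    for r, new in zip(lib, new_names):
        renamed.append(replace(r, id=new))
        entries.append(LedgerEntry(
            consensus_id=new, version=r.version, old_name=r.id, new_name=new,
            curator=curator, reviewer="", status=r.status,
            comment="renamed", timestamp=timestamp))
    return renamed, entries
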