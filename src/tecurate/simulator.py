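"""Synthetic TE families and genomes with truth annotations.

The simulator implants decayed copies of randomly generated elements into a
random background so every stage of the curation pipeline — copy mining,
consensus refinement, hallmark detection, classification, annotation
statistics — can be exercised end to end with known truth. Elements carry
planted TIR or LTR structure; insertions duplicate a target site (or only
the marked core of a target pattern, mimicking Tc4's duplication of the
central TNA of its CTNAG site); copies decay under a two-rate substitution
process with a transition:transversion ratio, small indels, and optional 5'
truncation.

`divergence` is the expected per-site proportion of substituted sites; with
ratio kappa, transitions have probability d*kappa/(kappa+1) and
transversions d/(kappa+1) per site, so `kimura2p` applied to those target
proportions is the closed-loop expectation for K2P parameter recovery.
Indels occur at `indel_factor` times the substitution rate with geometric
lengths; nested insertions are not modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from tecurate._dna import CODE_TO_SET, revcomp
from tecurate.seqio import AnnotationRow

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_PATTERN_RE = re.compile(r"^([A-Z]*)\[([A-Z]+)\]([A-Z]*)$")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _iupac_to_regex(pattern: str) -> str:
    return "".join(
        ch if len(CODE_TO_SET[ch]) == 1 else "[" + "".join(sorted(CODE_TO_SET[ch])) + "]"
        for ch in pattern)


def parse_target_pattern(pattern: str) -> tuple[str, str, str]:
    """Split e.g. ``C[TNA]G`` into (left context, duplicated core, right)."""
    m = _PATTERN_RE.match(pattern)
    if not m:
        raise ValueError(f"bad target-site pattern {pattern!r}; "
                         "expected like C[TNA]G")
    return m.group(1), m.group(2), m.group(3)


@dataclass
class FamilySpec:
    """Parameters of one simulated TE family."""

    name: str
    length: int = 800
    classification: str = "Unknown"
    tir_len: int = 0
    ltr_len: int = 0
    tsd_len: int = 0
    target_site_pattern: str | None = None  # e.g. "C[TNA]G"
    copy_number: int = 15
    divergence: float = 0.08
    ts_tv_ratio: float = 2.0
    truncation_prob: float = 0.1
    truncation_side: str = "5"  # "5", "3" or "both"
    indel_factor: float = 0.1
    indel_mean_len: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if self.tir_len and self.ltr_len:
            raise ValueError(f"{self.name}: TIRs and LTRs are mutually exclusive")
        if self.length < 2 * max(self.tir_len, self.ltr_len) + 1:
            raise ValueError(f"{self.name}: terminal repeats do not fit length")
        if self.target_site_pattern is not None:
            _, core, _ = parse_target_pattern(self.target_site_pattern)
            if len(core) != self.tsd_len:
                raise ValueError(
                    f"{self.name}: pattern core length {len(core)} != "
                    f"tsd_len {self.tsd_len}")


@dataclass
class TruthRow:
    """One implanted copy; coordinates 0-based half-open on the final genome."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    divergence: float  # realized substituted-site proportion
    tsd: str
    truncated: bool = False
    p: float = 0.0  # realized transition proportion
    q: float = 0.0  # realized transversion proportion


@dataclass
class SimulatedGenome:
    contigs: dict[str, str]
    truth: list[TruthRow]
    elements: dict[str, str]  # family -> undecayed element
    families: list[FamilySpec]


def simulate_family(spec: FamilySpec, rng: np.random.Generator | None = None) -> str:
    """The undecayed element sequence with planted terminal structure."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.tir_len:
        arm = _rand_seq(rng, spec.tir_len)
        mid = _rand_seq(rng, spec.length - 2 * spec.tir_len)
        return arm + mid + revcomp(arm)
    if spec.ltr_len:
        arm = _rand_seq(rng, spec.ltr_len)
        mid = _rand_seq(rng, spec.length - 2 * spec.ltr_len)
        return arm + mid + arm
    return _rand_seq(rng, spec.length)


@dataclass
class MutatedCopy:
    seq: str
    n_sites: int
    n_transitions: int
    n_transversions: int

    @property
    def divergence(self) -> float:
        return (self.n_transitions + self.n_transversions) / self.n_sites

    @property
    def p(self) -> float:
        return self.n_transitions / self.n_sites

    @property
    def q(self) -> float:
        return self.n_transversions / self.n_sites


def mutate_copy(element: str, divergence: float, ts_tv_ratio: float,
                rng: np.random.Generator, indel_factor: float = 0.0,
                indel_mean_len: float = 2.0) -> MutatedCopy:
    """Decay one copy: two-rate substitutions plus small geometric indels."""
    n = len(element)
    sub = rng.random(n) < divergence
    is_ts = rng.random(n) < ts_tv_ratio / (ts_tv_ratio + 1.0)
    indel = rng.random(n) < divergence * indel_factor
    out: list[str] = []
    ts = tv = 0
    i = 0
    geo_p = 1.0 / max(indel_mean_len, 1.0)
    while i < n:
        if indel[i]:
            length = int(rng.geometric(geo_p))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append(_rand_seq(rng, length))
        base = element[i]
        if sub[i] and base in _TRANSITION:
            if is_ts[i]:
                out.append(_TRANSITION[base])
                ts += 1
            else:
                out.append(_TRANSVERSIONS[base][int(rng.integers(0, 2))])
                tv += 1
        else:
            out.append(base)
        i += 1
    return MutatedCopy(seq="".join(out), n_sites=n, n_transitions=ts,
                       n_transversions=tv)


def _pick_positions(candidates: list[int], k: int, spacing: int,
                    occupied: list[int], rng: np.random.Generator) -> list[int]:
    order = list(rng.permutation(len(candidates)))
    chosen: list[int] = []
    for idx in order:
        pos = candidates[idx]
        if all(abs(pos - o) >= spacing for o in occupied + chosen):
            chosen.append(pos)
            if len(chosen) == k:
                return sorted(chosen)
    raise ValueError(f"could not place {k} copies with spacing {spacing}; "
                     f"only {len(chosen)} sites available")


def simulate_genome(families: list[FamilySpec], background_len: int = 120_000,
                    seed: int = 0, contig: str = "ctg1",
                    spacing: int = 4500, margin: int = 2200) -> SimulatedGenome:
    """A random genome with implanted, decayed TE copies plus truth.

    Insertion sites respect `spacing` (so each copy's 2 kb flanks stay
    copy-specific) and a `margin` from the contig ends. Families with a
    target-site pattern insert only at pattern matches, duplicating the
    marked core on both sides of the element; families with plain
    ``tsd_len`` duplicate the host bases at the insertion point. Output is
    bit-deterministic under `seed`.
    """
    rng = np.random.default_rng(seed)
    bg = _rand_seq(rng, background_len)
    elements: dict[str, str] = {}
    # (bg insertion point, inserted string, element span within insert, meta)
    planned: list[tuple[int, str, int, int, TruthRow]] = []
    occupied: list[int] = []
    for fam in families:
        element = simulate_family(fam, rng)
        elements[fam.name] = element
        if fam.target_site_pattern:
            left, core, right = parse_target_pattern(fam.target_site_pattern)
            rx = re.compile(_iupac_to_regex(left + core + right))
            sites = [m.start() + len(left) for m in rx.finditer(bg)
                     if margin < m.start() < background_len - margin]
            if len(sites) < fam.copy_number:
                raise ValueError(f"{fam.name}: no (or too few) matching "
                                 f"target sites for {fam.target_site_pattern}")
            cores = _pick_positions(sites, fam.copy_number, spacing, occupied, rng)
            points = [(c + fam.tsd_len, bg[c:c + fam.tsd_len]) for c in cores]
        else:
            cand = list(range(margin, background_len - margin))
            pos = _pick_positions(cand, fam.copy_number, spacing, occupied, rng)
            points = [(p, bg[p - fam.tsd_len:p] if fam.tsd_len else "")
                      for p in pos]
        occupied.extend(p for p, _ in points)
        for p, tsd in points:
            mut = mutate_copy(element, fam.divergence, fam.ts_tv_ratio, rng,
                              fam.indel_factor, fam.indel_mean_len)
            seq = mut.seq
            truncated = bool(rng.random() < fam.truncation_prob)
            if truncated:
                cut = int(len(seq) * rng.uniform(0.1, 0.5))
                side = fam.truncation_side
                if side == "both":
                    side = "5" if rng.random() < 0.5 else "3"
                seq = seq[cut:] if side == "5" else seq[:len(seq) - cut]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            row = TruthRow(contig=contig, start=-1, end=-1, strand=strand,
                           family=fam.name, divergence=mut.divergence,
                           tsd=tsd, truncated=truncated, p=mut.p, q=mut.q)
            planned.append((p, seq + tsd, 0, len(seq), row))
    planned.sort(key=lambda t: t[0])
    parts: list[str] = []
    cur = 0
    out_len = 0
    truth: list[TruthRow] = []
    for p, ins, e0, e1, row in planned:
        parts.append(bg[cur:p])
        out_len += p - cur
        row.start = out_len + e0
        row.end = out_len + e1
        parts.append(ins)
        out_len += len(ins)
        cur = p
        truth.append(row)
    parts.append(bg[cur:])
    genome = "".join(parts)
    return SimulatedGenome(contigs={contig: genome}, truth=truth,
                           elements=elements, families=list(families))


def make_raw_consensus(element: str, rng: np.random.Generator,
                       keep_frac: float = 0.7, divergence: float = 0.02,
                       truncate_from: str = "3") -> str:
    """Emulate an automatically generated draft consensus: a truncated,
    slightly noisy fragment of the true element."""
    keep = max(1, int(len(element) * keep_frac))
    frag = element[:keep] if truncate_from == "3" else element[-keep:]
    return mutate_copy(frag, divergence, 2.0, rng).seq


def project_truth_to_out(sim: SimulatedGenome,
                         score_scale: float = 1000.0) -> list[AnnotationRow]:
    """Project truth annotations into the ``.out`` dialect.

    pct_div carries the realized per-copy substitution divergence (x100,
    rounded to the dialect's one decimal) so annotation statistics can be
    tested without a masking engine.
    """
    class_of = {f.name: f.classification for f in sim.families}
    elen = {name: len(e) for name, e in sim.elements.items()}
    rows = []
    for t in sim.truth:
        contig_len = len(sim.contigs[t.contig])
        span = t.end - t.start
        rows.append(AnnotationRow(
            score=round(score_scale * (1.0 - t.divergence)),
            pct_div=round(100.0 * t.divergence, 1), pct_del=0.0, pct_ins=0.0,
            query=t.contig, qbegin=t.start + 1, qend=t.end,
            qleft=contig_len - t.end, strand=t.strand,
            repeat_name=t.family, repeat_classification=class_of[t.family],
            rbegin=1, rend=min(span, elen[t.family]),
            rleft=max(0, elen[t.family] - span),
        ))
    return rows
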