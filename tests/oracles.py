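"""Independent brute-force statements of the consensus rules, used as
oracles against the implementation (exact arithmetic, no shared code)."""

from fractions import Fraction
from itertools import combinations_with_replacement

from tecurate.consensus_builder import MSA

IUPAC = {frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
         frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
         frozenset("CG"): "S", frozenset("AT"): "W", frozenset("GT"): "K",
         frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
         frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N"}


def oracle_column(profile: dict) -> str:
    """Majority rule, restated: gap if gaps exceed half of all rows; the
    top base if it strictly exceeds half the non-gap depth; else the
    ambiguity code of bases at >= a quarter of the depth; else N."""
    total = sum(profile.values())
    gaps = profile.get("-", 0)
    if Fraction(gaps, total) > Fraction(1, 2):
        return "-"
    depth = total - gaps
    if depth == 0:
        return "-"
    freqs = {b: Fraction(profile.get(b, 0), depth) for b in "ACGT"}
    top = max(freqs.values())
    if top > Fraction(1, 2):
        return max("ACGT", key=lambda b: freqs[b])
    qualified = frozenset(b for b in "ACGT"
                          if freqs[b] >= Fraction(1, 4) and freqs[b] > 0)
    if not qualified:
        return "N"
    return IUPAC[qualified]


def all_profiles(max_depth=6):
    for depth in range(1, max_depth + 1):
        for combo in combinations_with_replacement("ACGTN-", depth):
            profile = {}
            for ch in combo:
                profile[ch] = profile.get(ch, 0) + 1
            yield profile


def region_msa(residue_counts, width=None):
    """An MSA whose rows place `residue_counts[i]` residues (all A) in a
    region flanked by anchored C columns."""
    width = width or max(residue_counts)
    rows = [("anchor", "CC" + "A" * width + "CC")]
    for i, k in enumerate(residue_counts):
        rows.append((f"r{i}", "CC" + "A" * k + "-" * (width - k) + "CC"))
    return MSA(rows=rows, anchor_index=0), (2, 2 + width)


def oracle_indel(residue_counts):
    """Indel-event rule, restated: >4 distinct length classes or no class
    reaching a third of the rows -> 10-N placeholder; else plurality
    length, ties to the shorter."""
    classes = {}
    for k in residue_counts:
        classes[k] = classes.get(k, 0) + 1
    n = len(residue_counts)
    if len(classes) > 4 or max(classes.values()) < Fraction(n, 3):
        return "placeholder"
    best = max(classes.values())
    return min(k for k, c in classes.items() if c == best)
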