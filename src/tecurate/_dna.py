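"""Small DNA utilities shared across modules: IUPAC codes, complements, encoding."""

from __future__ import annotations

import numpy as np

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

# base-set (frozenset of ACGT) -> ambiguity code
_SET_TO_CODE = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
CODE_TO_SET = {v: set(k) for k, v in _SET_TO_CODE.items()}
CODE_TO_SET["N"] = set("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-",
)


def iupac_code(bases) -> str:
    """Ambiguity code for a non-empty set of unambiguous bases."""
    key = frozenset(bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    return _SET_TO_CODE[key]


def matches_iupac(base: str, code: str) -> bool:
    """True if unambiguous `base` is compatible with IUPAC `code`."""
    return base in CODE_TO_SET.get(code, set())


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Upper-case, map U->T; validate against the IUPAC DNA alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
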