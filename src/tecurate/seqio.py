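"""Readers and writers for every format the toolkit touches.

Dialects handled: FASTA libraries with ``name#Class/Superfamily`` headers
(RepeatMasker library convention), aligned FASTA MSAs, the RepeatMasker
``.out`` annotation table, the common 12-column tab-separated hit table, and
the TSV curation ledger. Internal coordinates are 0-based half-open; the
``.out`` and hit dialects are 1-based inclusive and are kept as such on the
row objects (they mirror the files), with conversion happening where the
toolkit consumes them.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace  # noqa: F401  (replace is part of the API surface)
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tecurate._dna import IUPAC_DNA, normalize_seq

FASTA_WRAP = 60

STATUSES = ("raw", "curated", "in_review", "accepted", "returned")


@dataclass
class ConsensusRecord:
    """A TE consensus sequence with classification, provenance and version."""

    id: str
    classification: str = "Unknown"
    sequence: str = ""
    version: int = 1
    status: str = "raw"
    curator: str | None = None
    reviewer: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = normalize_seq(self.sequence)
        if self.version < 1:
            raise ValueError(f"{self.id}: version must be >= 1")
        if self.status not in STATUSES:
            raise ValueError(f"{self.id}: unknown status {self.status!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        return f"{self.id}#{self.classification}"


@dataclass
class AnnotationRow:
    """One masked-repeat interval in the RepeatMasker ``.out`` dialect.

    Query coordinates are 1-based inclusive as in the file; strand is
    normalized to ``+``/``-`` (the file encodes minus as ``C``), and the
    minus-strand swap of repeat begin/left is undone on read.
    """

    score: float
    pct_div: float
    pct_del: float
    pct_ins: float
    query: str
    qbegin: int
    qend: int
    qleft: int
    strand: str
    repeat_name: str
    repeat_classification: str
    rbegin: int
    rend: int
    rleft: int

    def __post_init__(self):
        if self.qbegin > self.qend:
            raise ValueError(f"{self.query}: qbegin > qend")
        if self.pct_div < 0:
            raise ValueError(f"{self.query}: negative divergence")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.qend - self.qbegin + 1

    @property
    def category(self) -> str:
        return self.repeat_classification.split("/")[0]


@dataclass
class HitRow:
    """One row of the 12-column tabular search output (1-based inclusive).

    ``sstart > send`` encodes a minus-strand hit. When hits come from the
    internal aligner the ``bitscore`` field carries its raw affine score.
    """

    query: str
    subject: str
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")

    @property
    def strand(self) -> str:
        return "-" if self.sstart > self.send else "+"


@dataclass
class LedgerEntry:
    """One append-only row of the curation ledger."""

    consensus_id: str
    version: int
    old_name: str
    new_name: str
    curator: str
    reviewer: str
    status: str
    comment: str
    timestamp: str
    prev_hash: str = ""
    entry_hash: str = ""


LEDGER_COLUMNS = [
    "consensus_id", "version", "old_name", "new_name", "curator",
    "reviewer", "status", "comment", "timestamp", "prev_hash", "entry_hash",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[ConsensusRecord]:
    """Read a FASTA library; header text after ``#`` is the classification.

    A header without ``#`` yields classification ``Unknown`` with a warning.
    Lower-case sequence is upper-cased and U mapped to T.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "#" in name:
            rid, classification = name.split("#", 1)
        else:
            rid, classification = name, "Unknown"
            warnings.warn(f"{name}: no '#classification' in header; set to Unknown")
        records.append(ConsensusRecord(id=rid, classification=classification,
                                       sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ConsensusRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.header, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqs)


def read_plain_fasta(path) -> list[tuple[str, str]]:
    """(label, sequence) pairs without library-header interpretation."""
    return [(rec.id, normalize_seq(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def write_plain_fasta(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for label, seq in pairs:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------- MSA

def read_msa(path) -> list[tuple[str, str]]:
    """Aligned FASTA; all rows must have identical length."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_DNA - {"-"}
        if bad:
            raise ValueError(f"{rec.id}: non-IUPAC characters {sorted(bad)}")
        rows.append((rec.id, seq))
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError(f"{path}: ragged alignment rows (lengths {sorted(lengths)})")
    return rows


def write_msa(rows: Iterable[tuple[str, str]], path) -> None:
    rows = list(rows)
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError("refusing to write ragged alignment")
    write_plain_fasta(rows, path)


# ---------------------------------------------------------------- .out

def _paren_int(tok: str) -> int:
    return int(tok.strip("()"))


def read_rm_out(path) -> list[AnnotationRow]:
    """Parse the RepeatMasker ``.out`` dialect (3-line header, then records).

    Minus-strand rows (``C``) have their repeat begin/left fields swapped in
    the file; they are normalized here. A trailing ID column and overlap
    star are tolerated.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        toks = line.split()
        if toks[-1] == "*":
            toks = toks[:-1]
        if len(toks) == 15:  # trailing ID
            toks = toks[:-1]
        if len(toks) != 14:
            raise ValueError(f"{path}:{lineno}: expected 14-16 columns, got {len(toks)}")
        strand = toks[8]
        if strand == "C":
            strand = "-"
            rleft, rend, rbegin = _paren_int(toks[11]), int(toks[12]), int(toks[13])
        elif strand == "+":
            rbegin, rend, rleft = int(toks[11]), int(toks[12]), _paren_int(toks[13])
        else:
            raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
        rows.append(AnnotationRow(
            score=float(toks[0]), pct_div=float(toks[1]), pct_del=float(toks[2]),
            pct_ins=float(toks[3]), query=toks[4], qbegin=int(toks[5]),
            qend=int(toks[6]), qleft=_paren_int(toks[7]), strand=strand,
            repeat_name=toks[9], repeat_classification=toks[10],
            rbegin=rbegin, rend=rend, rleft=rleft,
        ))
    return rows


def write_rm_out(rows: Iterable[AnnotationRow], path) -> None:
    """Write rows back to the ``.out`` dialect (round-trips with read_rm_out)."""
    header = (
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat       position in repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat"
        "  class/family  begin end  (left)\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for r in rows:
            if r.strand == "+":
                s, rb, re_, rl = "+", str(r.rbegin), str(r.rend), f"({r.rleft})"
            else:
                s, rb, re_, rl = "C", f"({r.rleft})", str(r.rend), str(r.rbegin)
            fh.write(
                f"{r.score:>6g} {r.pct_div:5.1f} {r.pct_del:4.1f} {r.pct_ins:4.1f}  "
                f"{r.query}  {r.qbegin} {r.qend} ({r.qleft})  {s}  "
                f"{r.repeat_name}  {r.repeat_classification}  {rb} {re_} {rl}\n"
            )


# ---------------------------------------------------------------- hit table

def read_hits(path) -> list[HitRow]:
    """12-column tab-separated search output."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(toks)}")
            rows.append(HitRow(
                query=toks[0], subject=toks[1], identity=float(toks[2]),
                aln_length=int(toks[3]), mismatches=int(toks[4]),
                gap_opens=int(toks[5]), qstart=int(toks[6]), qend=int(toks[7]),
                sstart=int(toks[8]), send=int(toks[9]), evalue=float(toks[10]),
                bitscore=float(toks[11]),
            ))
    return rows


def write_hits(rows: Iterable[HitRow], path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in (
                r.query, r.subject, r.identity, r.aln_length, r.mismatches,
                r.gap_opens, r.qstart, r.qend, r.sstart, r.send,
                r.evalue, r.bitscore)) + "\n")


# ---------------------------------------------------------------- ledger TSV

def read_ledger(path) -> list[LedgerEntry]:
    """TSV ledger with fixed header.

    A consensus version accumulates one entry per review event; replaying
    the same event for the same version is a duplicate, so the key
    (consensus_id, version, status) must be unique.
    """
    entries = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != LEDGER_COLUMNS:
            raise ValueError(f"{path}: unexpected ledger header {reader.fieldnames}")
        for row in reader:
            key = (row["consensus_id"], int(row["version"]), row["status"])
            if key in seen:
                raise ValueError(f"{path}: duplicated ledger key {key}")
            seen.add(key)
            entries.append(LedgerEntry(
                consensus_id=row["consensus_id"], version=int(row["version"]),
                old_name=row["old_name"], new_name=row["new_name"],
                curator=row["curator"], reviewer=row["reviewer"],
                status=row["status"], comment=row["comment"],
                timestamp=row["timestamp"], prev_hash=row["prev_hash"],
                entry_hash=row["entry_hash"],
            ))
    return entries


def write_ledger(entries: Iterable[LedgerEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LEDGER_COLUMNS)
        for e in entries:
            writer.writerow([getattr(e, c) for c in LEDGER_COLUMNS])
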