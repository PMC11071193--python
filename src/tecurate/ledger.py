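"""Curation bookkeeping: the peer-review state machine and version control.

Every consensus moves through raw -> curated -> in_review -> accepted or
returned (returned -> curated re-enters the loop); acceptance requires a
reviewer distinct from the curator. Each transition appends a hash-chained
entry to a TSV ledger (the self-hosted equivalent of the shared review
spreadsheet), and every new consensus version is added to the family's
alignment file next to the older ones so decisions stay auditable.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from tecurate.align import align
from tecurate.consensus_builder import GAP, MSA
from tecurate.seqio import ConsensusRecord, LedgerEntry

TRANSITIONS: dict[tuple[str, str], str] = {
    ("raw", "curate"): "curated",
    ("curated", "submit"): "in_review",
    ("in_review", "accept"): "accepted",
    ("in_review", "return"): "returned",
    ("returned", "recurate"): "curated",
}


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def entry_hash(entry: LedgerEntry) -> str:
    payload = "\t".join([
        entry.consensus_id, str(entry.version), entry.old_name,
        entry.new_name, entry.curator, entry.reviewer, entry.status,
        entry.comment, entry.timestamp, entry.prev_hash,
    ])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReviewState:
    """Review status of one consensus plus its append-only history."""

    consensus_id: str
    state: str = "raw"
    curator: str = ""
    version: int = 1
    history: list[LedgerEntry] = field(default_factory=list)


def transition(state: ReviewState, event: str, actor: str,
               comment: str = "", timestamp: str | None = None) -> ReviewState:
    """Apply one review event, appending a hash-chained ledger entry.

    Illegal events raise, naming the allowed ones; accepting one's own
    curation is rejected.
    """
    key = (state.state, event)
    if key not in TRANSITIONS:
        allowed = sorted(e for (s, e) in TRANSITIONS if s == state.state)
        raise ValueError(
            f"{state.consensus_id}: event {event!r} illegal from state "
            f"{state.state!r}; allowed: {allowed or 'none (terminal)'}")
    if event == "accept" and actor == state.curator:
        raise ValueError(
            f"{state.consensus_id}: reviewer must differ from curator {actor!r}")
    new_state = TRANSITIONS[key]
    curator = actor if event in ("curate", "recurate") else state.curator
    version = state.version + 1 if event == "recurate" else state.version
    prev = state.history[-1].entry_hash if state.history else ""
    entry = LedgerEntry(
        consensus_id=state.consensus_id, version=version,
        old_name=state.consensus_id, new_name=state.consensus_id,
        curator=curator,
        reviewer=actor if event in ("accept", "return") else "",
        status=new_state, comment=comment,
        timestamp=timestamp or _now(), prev_hash=prev)
    entry.entry_hash = entry_hash(entry)
    return ReviewState(consensus_id=state.consensus_id, state=new_state,
                       curator=curator, version=version,
                       history=state.history + [entry])


def verify_chain(entries: list[LedgerEntry]) -> bool:
    """Recompute the hash chain; False on any tampered or reordered entry."""
    prev = ""
    for e in entries:
        if e.prev_hash != prev or entry_hash(e) != e.entry_hash:
            return False
        prev = e.entry_hash
    return True


def audit_accepted(entries: list[LedgerEntry]) -> list[str]:
    """Ids of accepted consensuses lacking a reviewer distinct from the
    curator (should be empty for a well-formed ledger)."""
    bad = []
    for e in entries:
        if e.status == "accepted" and (not e.reviewer or e.reviewer == e.curator):
            bad.append(e.consensus_id)
    return bad


def assign_reviewers(curators: list[str], strategy: str = "random",
                     reviewers: list[str] | None = None,
                     seed: int = 0) -> dict[str, str]:
    """Reviewer assignment: ``random`` derangement among curators (each
    reviews someone else's work) or ``fixed`` round-robin over a reviewer
    panel."""
    if strategy == "fixed":
        if not reviewers:
            raise ValueError("fixed strategy needs a reviewer panel")
        return {c: reviewers[i % len(reviewers)]
                for i, c in enumerate(curators)}
    if strategy != "random":
        raise ValueError(f"unknown strategy {strategy!r}")
    if len(curators) < 2:
        raise ValueError("random assignment needs at least two curators")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(len(curators)))
    while any(i == p for i, p in enumerate(perm)):  # force a derangement
        perm = list(rng.permutation(len(curators)))
    return {c: curators[perm[i]] for i, c in enumerate(curators)}


_VERSION_LABEL = re.compile(r"^(?P<id>.+)\.v(?P<version>\d+)$")


def parse_version_label(label: str) -> tuple[str, int]:
    m = _VERSION_LABEL.match(label)
    if not m:
        raise ValueError(f"not a versioned row label: {label!r}")
    return m.group("id"), int(m.group("version"))


def snapshot_version(record: ConsensusRecord, msa: MSA) -> MSA:
    """Append a consensus version to its family alignment as ``id.vN``.

    The sequence is projected onto the existing column system by aligning
    it to the degapped anchor row; residues the coordinate system cannot
    hold (insertions with no anchor-gap column available) are dropped from
    the projection (never from the record). Earlier versions are never
    removed; re-adding an existing version is an error.
    """
    label = f"{record.id}.v{record.version}"
    if any(lab == label for lab, _ in msa.rows):
        raise ValueError(f"version row {label} already present")
    anchor_row = msa.rows[msa.anchor_index][1]
    anchor_seq = anchor_row.replace(GAP, "")
    res = align(record.sequence, anchor_seq, mode="glocal")
    # anchor residue index -> MSA column
    col_of = [j for j, ch in enumerate(anchor_row) if ch != GAP]
    out = [GAP] * len(anchor_row)
    i, j = res.a_start, res.b_start
    for ca, cb in zip(res.aligned_a, res.aligned_b):
        if ca != GAP and cb != GAP:
            out[col_of[j]] = record.sequence[i]
            i += 1
            j += 1
        elif ca == GAP:
            j += 1
        else:  # insertion relative to the anchor: use free gap columns
            if j < len(col_of):
                lo = col_of[j - 1] + 1 if j > 0 else 0
                for c in range(lo, col_of[j]):
                    if out[c] == GAP:
                        out[c] = record.sequence[i]
                        break
            i += 1
    return MSA(rows=msa.rows + [(label, "".join(out))],
               anchor_index=msa.anchor_index)
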