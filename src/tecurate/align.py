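"""Internal pairwise aligner: affine-gap Gotoh DP plus seed-and-extend search.

Three alignment modes are exposed:

* ``local``  — Smith-Waterman (used for hit extension, TIR/LTR search);
* ``glocal`` — global with cost-free terminal gaps in either sequence
  (used to anchor extended copies on a consensus; tolerates both flanking
  sequence and truncated copies);
* ``global`` — Needleman-Wunsch;
* ``extend`` — anchored at the start of both sequences, ends wherever the
  score peaks (used to align segments that share a known junction, e.g.
  copy sequence continuing past a truncated anchor's end).

Default scoring is match +1, mismatch -2, gap open -5, gap extend -1
(a gap of length L costs open + L*extend). The seed-and-extend search
(`find_local_hits`) seeds on exact k-mers, clusters seeds by diagonal and
runs one banded-window local alignment per cluster; it backs the internal
copy search and library comparison at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from tecurate._dna import encode

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXT = -1

_MODES = {"local": 0, "glocal": 1, "global": 2, "extend": 3}

_NEG = -(1 << 29)


@njit(cache=True, nogil=True)
def _gotoh(a, b, match, mismatch, go, ge, mode):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    if mode == 2 or mode == 3:
        for j in range(1, m + 1):
            H[0, j] = go + ge * j
            E[0, j] = H[0, j]
        for i in range(1, n + 1):
            H[i, 0] = go + ge * i
            F[i, 0] = H[i, 0]
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + ge
            t = H[i, j - 1] + go + ge
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] + ge
            t = H[i - 1, j] + go + ge
            if t > f:
                f = t
            F[i, j] = f
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if mode == 0:
                if h < 0:
                    h = 0
                if h > best:
                    best = h
                    bi = i
                    bj = j
            elif mode == 3 and h > best:
                best = h
                bi = i
                bj = j
            H[i, j] = h
    if mode == 1:
        best = _NEG
        for j in range(m + 1):
            if H[n, j] >= best:
                best = H[n, j]
                bi = n
                bj = j
        for i in range(n + 1):
            if H[i, m] > best:
                best = H[i, m]
                bi = i
                bj = m
    elif mode == 2:
        best = H[n, m]
        bi = n
        bj = m
    # traceback: ops 0=diag, 1=up (consume a), 2=left (consume b), reversed
    ops = np.empty(n + m + 2, np.uint8)
    k = 0
    i = bi
    j = bj
    state = 0
    while True:
        if state == 0:
            if i == 0 and j == 0:
                break
            if mode == 0 and H[i, j] == 0:
                break
            if i == 0:
                if mode >= 2:
                    for _ in range(j):
                        ops[k] = 2
                        k += 1
                    j = 0
                break
            if j == 0:
                if mode >= 2:
                    for _ in range(i):
                        ops[k] = 1
                        k += 1
                    i = 0
                break
            ai = a[i - 1]
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                break
        elif state == 1:
            ops[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] + go + ge:
                state = 0
            j -= 1
        else:
            ops[k] = 1
            k += 1
            if F[i, j] == H[i - 1, j] + go + ge:
                state = 0
            i -= 1
    return best, i, j, bi, bj, ops[:k]


@dataclass
class AlignmentResult:
    """One pairwise alignment; coordinates 0-based half-open on the inputs."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str
    matches: int
    mismatches: int
    gap_opens: int
    gap_cols: int

    @property
    def n_cols(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        return self.matches / self.n_cols if self.n_cols else 0.0


def align(a: str, b: str, mode: str = "local", match: int = DEFAULT_MATCH,
          mismatch: int = DEFAULT_MISMATCH, gap_open: int = DEFAULT_GAP_OPEN,
          gap_ext: int = DEFAULT_GAP_EXT) -> AlignmentResult:
    """Align two sequences; see module docstring for the modes."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    score, a0, b0, a1, b1, rev_ops = _gotoh(
        encode(a), encode(b), match, mismatch, gap_open, gap_ext, _MODES[mode]
    )
    ops = rev_ops[::-1]
    pa, pb = [], []
    i, j = a0, b0
    matches = mismatches = gap_opens = gap_cols = 0
    prev_gap = False
    for op in ops:
        if op == 0:
            ca, cb = a[i], b[j]
            pa.append(ca)
            pb.append(cb)
            if ca == cb and ca in "ACGT":
                matches += 1
            else:
                mismatches += 1
            i += 1
            j += 1
            prev_gap = False
        elif op == 1:
            pa.append(a[i])
            pb.append("-")
            i += 1
            gap_cols += 1
            if not prev_gap:
                gap_opens += 1
            prev_gap = True
        else:
            pa.append("-")
            pb.append(b[j])
            j += 1
            gap_cols += 1
            if not prev_gap:
                gap_opens += 1
            prev_gap = True
    return AlignmentResult(
        score=int(score), a_start=a0, a_end=a1, b_start=b0, b_end=b1,
        aligned_a="".join(pa), aligned_b="".join(pb),
        matches=matches, mismatches=mismatches,
        gap_opens=gap_opens, gap_cols=gap_cols,
    )


@dataclass
class LocalHit:
    """Seed-and-extend local hit of `query` on `target` (0-based half-open)."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    mismatches: int
    gap_opens: int
    n_cols: int

    @property
    def identity(self) -> float:
        return self.matches / self.n_cols if self.n_cols else 0.0


def find_local_hits(query: str, target: str, k: int = 11, min_score: int = 30,
                    band: int = 32, pad: int = 64,
                    scoring: dict | None = None) -> list[LocalHit]:
    """All well-scoring local alignments of `query` within `target`.

    Exact k-mer seeds are clustered by diagonal (within `band`) and target
    proximity; each cluster is resolved by one local alignment of the query
    against a padded target window. Hits with identical target spans are
    deduplicated; ordering is score desc, then (t_start, q_start).
    """
    if len(query) < k:
        raise ValueError(f"query shorter than seed length k={k}")
    scoring = scoring or {}
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i:i + k], []).append(i)
    seeds = []  # (diag, tpos, qpos)
    for t in range(len(target) - k + 1):
        for q in index.get(target[t:t + k], ()):
            seeds.append((t - q, t, q))
    if not seeds:
        return []
    seeds.sort()
    max_gap = len(query)
    clusters: list[list[tuple[int, int, int]]] = []
    for s in seeds:
        placed = False
        if clusters:
            last = clusters[-1][-1]
            if abs(s[0] - last[0]) <= band and abs(s[1] - last[1]) <= max_gap:
                clusters[-1].append(s)
                placed = True
        if not placed:
            clusters.append([s])
    hits: dict[tuple[int, int], LocalHit] = {}
    for cl in clusters:
        t0 = max(0, min(t - q for _, t, q in cl) - pad)
        t1 = min(len(target), max(t + (len(query) - q) for _, t, q in cl) + pad)
        if t1 - t0 < k:
            continue
        res = align(query, target[t0:t1], mode="local", **scoring)
        if res.score < min_score or res.n_cols < k:
            continue
        key = (t0 + res.b_start, t0 + res.b_end)
        hit = LocalHit(
            score=res.score, q_start=res.a_start, q_end=res.a_end,
            t_start=key[0], t_end=key[1], matches=res.matches,
            mismatches=res.mismatches, gap_opens=res.gap_opens,
            n_cols=res.n_cols,
        )
        if key not in hits or hit.score > hits[key].score:
            hits[key] = hit
    out = sorted(hits.values(), key=lambda h: (-h.score, h.t_start, h.q_start))
    return out
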