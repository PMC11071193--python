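"""Structural hallmark detection: TIRs, LTRs, TSDs and boundary logos.

Hallmarks are what turn a "repetitive element" into a classifiable
transposable element: terminal inverted repeats flank most DNA transposons,
long terminal repeats flank LTR retrotransposons, and a target site
duplication (a short host motif copied to both sides on insertion) marks
transposition for the vast majority of TEs. Some families duplicate only
part of their target — Tc4 elements cut the interrupted palindrome CTNAG
and duplicate only the central TNA — which the context-extended target-site
model captures without special-casing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from tecurate._dna import iupac_code, revcomp
from tecurate.align import align
from tecurate.consensus_builder import column_consensus


@dataclass
class TIRReport:
    five: tuple[int, int]   # 5' arm, element coords, 0-based half-open
    three: tuple[int, int]  # 3' arm
    length: int             # alignment columns
    mismatches: int         # mismatch + gap columns


@dataclass
class LTRReport:
    five: tuple[int, int]
    three: tuple[int, int]
    length: int
    identity: float


@dataclass
class TSDCall:
    """Per-copy target site duplication call."""

    left: str
    right: str
    length: int
    shift: tuple[int, int] = (0, 0)
    left_flank: str = ""   # flank at the calling shift (context for models)
    right_flank: str = ""


@dataclass
class TSDReport:
    calls: list[TSDCall]
    consensus_length: int
    motif: str                    # IUPAC consensus of the called strings
    boundary_shift: tuple[int, int] = (0, 0)


@dataclass
class TargetSiteModel:
    """Reconstructed pre-insertion target pattern (TSD core counted once)."""

    pattern: str    # e.g. CTNAG
    core: str       # the duplicated part, e.g. TNA
    annotated: str  # cut annotation, e.g. C|TNA|G


@dataclass
class PositionLogo:
    """Per-position base frequencies and information content (bits)."""

    window: str
    freqs: np.ndarray  # n_pos x 4, columns A,C,G,T
    ic: np.ndarray     # n_pos, in [0, 2]
    n_seqs: int


@dataclass
class HallmarkReport:
    tir: TIRReport | None = None
    ltr: LTRReport | None = None
    tsd: TSDReport | None = None
    target_site_model: TargetSiteModel | None = None
    notes: list[str] = field(default_factory=list)


# --------------------------------------------------------------- TIR / LTR

def find_tir(element: str, min_len: int = 8, max_mismatch_frac: float = 0.2,
             max_offset: int = 30) -> TIRReport | None:
    """Best terminal-inverted-repeat pair, or None.

    Locally aligns the 5' end region against the reverse complement of the
    3' end region; reported when the arm is long enough, clean enough, and
    both arms start within `max_offset` of their terminus.
    """
    L = len(element)
    if L < 2 * min_len:
        return None
    w = min(max_offset + 50, L // 2)
    head = element[:w]
    tail_rc = revcomp(element[-w:])
    res = align(head, tail_rc, mode="local")
    if res.n_cols < min_len:
        return None
    mism = res.mismatches + res.gap_cols
    if mism > max_mismatch_frac * res.n_cols:
        return None
    if res.a_start > max_offset or res.b_start > max_offset:
        return None
    # rc(tail) position i corresponds to element position L-1-i
    three = (L - res.b_end, L - res.b_start)
    return TIRReport(five=(res.a_start, res.a_end), three=three,
                     length=res.n_cols, mismatches=mism)


def find_ltr(element: str, min_len: int = 80, min_identity: float = 0.8,
             max_offset: int = 50, max_ltr: int = 1000) -> LTRReport | None:
    """Best direct terminal repeat pair (LTR candidate), or None."""
    L = len(element)
    if L < 2 * min_len:
        return None
    w = min(max_offset + max_ltr, L // 2)
    head = element[:w]
    tail = element[-w:]
    res = align(head, tail, mode="local")
    if res.n_cols < min_len:
        return None
    if res.identity < min_identity:
        return None
    if res.a_start > max_offset or res.b_end < w - max_offset:
        return None
    off = L - w
    return LTRReport(five=(res.a_start, res.a_end),
                     three=(off + res.b_start, off + res.b_end),
                     length=res.n_cols, identity=res.identity)


# --------------------------------------------------------------- TSD

def _tsd_match(left: str, right: str, m: int,
               allow_mismatch: bool = True) -> bool:
    """Does the left-flank suffix of length m duplicate the right-flank
    prefix? One internal mismatch is allowed for m >= 8 (post-insertion
    mutation); the boundary-defining first and last characters must match
    exactly."""
    if m < 1 or len(left) < m or len(right) < m:
        return False
    a, b = left[-m:], right[:m]
    if a == b:
        return True
    if not allow_mismatch or m < 8 or a[0] != b[0] or a[-1] != b[-1]:
        return False
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return mism <= 1


def _longest_suffix_prefix(left: str, right: str, min_len: int,
                           max_len: int) -> int:
    """Longest m in [min_len, max_len] with a qualifying suffix/prefix match."""
    hi = min(max_len, len(left), len(right))
    for m in range(hi, min_len - 1, -1):
        if _tsd_match(left, right, m):
            return m
    return 0


def _iupac_columns(strings: list[str]) -> str:
    """Majority/ambiguity call per column (frequency rule) — for noisy
    context positions."""
    return "".join(
        column_consensus(Counter(s[p] for s in strings))
        for p in range(len(strings[0])))


def _iupac_observed(strings: list[str]) -> str:
    """Ambiguity code of the bases observed per column — for motif strings
    whose characters are verified duplication content (a target-site motif
    like TNA means "any base was seen here", not "no base was frequent")."""
    out = []
    for p in range(len(strings[0])):
        bases = {s[p] for s in strings} & set("ACGT")
        out.append(iupac_code(bases) if bases else "N")
    return "".join(out)


def _shift_range(m: int, max_shift: int, max_borrow: int) -> tuple[int, int]:
    """(trim, borrow) ranges allowed when testing a TSD of length m.

    Detected termini wobble by a few bp per copy — flanks may hold
    terminal element bases (fixed by trimming the flank inward) or the
    element may have absorbed the duplication (fixed by borrowing element
    bases back out). The ranges scale with m so the chance-match level
    stays manageable; what actually controls false calls is the decoy
    calibration in `find_tsd`."""
    if m <= 2:
        return 0, 0
    if m == 3:
        return min(2, max_shift), min(2, max_borrow)
    if m == 4:
        return min(4, max_shift), min(4, max_borrow)
    if m == 5:
        return min(6, max_shift), min(6, max_borrow)
    return max_shift, max_borrow


DECOY_OFFSET = 12  # beyond any boundary adjustment, so decoys hold no TSD


def _flanks_at(copy, dl: int, dr: int):
    left, elem, right = copy
    lx = left + elem[:dl] if dl >= 0 else left[:len(left) + dl]
    rx = right[dr:] if dr >= 0 else elem[len(elem) + dr:] + right
    return lx, rx


def _best_match(copy, m: int, max_shift: int, max_borrow: int):
    """Smallest qualifying boundary adjustment for a length-m duplication.

    dl < 0 / dr > 0 trim flank bases (terminal element bases were left in
    the flanks); dl > 0 / dr < 0 borrow element bases back (the element
    absorbed the duplication). The one-mismatch tolerance for long
    duplications applies only at the unshifted boundary — combined with
    shift freedom it would admit far too many near-matches."""
    s, b = _shift_range(m, max_shift, max_borrow)
    for dl in sorted(range(-s, b + 1), key=abs):
        for dr in sorted(range(-b, s + 1), key=abs):
            lx, rx = _flanks_at(copy, dl, dr)
            if _tsd_match(lx, rx, m, allow_mismatch=(dl == 0 and dr == 0)):
                return (dl, dr), lx, rx
    return None


def find_tsd(copies_with_flanks: list[tuple[str, str, str]], min_len: int = 2,
             max_len: int = 20, max_shift: int = 10, max_borrow: int = 6,
             support_frac: float = 0.55,
             excess_frac: float = 0.25) -> TSDReport:
    """Call target site duplications from per-copy flanks.

    Detected termini are only accurate to a few bp per copy, so each copy
    may match a candidate duplication under a small boundary adjustment
    (trimming flank bases back out of the element or vice versa). The
    consensus TSD length is the longest m matched by at least
    `support_frac` of the copies — any shorter suffix of a true TSD is
    matched by every copy, so the longest well-supported length, not the
    per-copy plurality, identifies the duplication.

    The boundary-adjustment freedom lets chance matches accumulate, so two
    guards calibrate the call. First, an empirical null: the same search
    run on decoy junctions taken `DECOY_OFFSET` bp further out in the
    flanks, where no duplication exists; support must exceed the decoy
    support by `excess_frac` of the copies. Second, a plateau rule:
    support is near-constant for every length up to the true one and
    cliffs just above it (a spurious one-base extension is only carried by
    the subset of copies with a flanking-base coincidence), so the called
    length must retain at least 75% of the best support among qualifying
    lengths. The motif is the IUPAC consensus of the supporting strings.
    """
    uniq = list(dict.fromkeys(copies_with_flanks))  # collapse identical loci
    n = len(uniq)
    decoys = [(left[:-DECOY_OFFSET], elem, right[DECOY_OFFSET:])
              for left, elem, right in uniq
              if len(left) >= DECOY_OFFSET + max_len
              and len(right) >= DECOY_OFFSET + max_len]
    use_decoy = len(decoys) >= max(3, 0.8 * n)

    candidates: list[tuple[int, list]] = []
    for m in range(max_len, min_len - 1, -1):
        found = [(copy, _best_match(copy, m, max_shift, max_borrow))
                 for copy in uniq]
        hits = [(copy, f) for copy, f in found if f is not None]
        # candidates of 3 bp or less are cheap to match by chance and a
        # real short TSD is matched by essentially every copy, so they
        # need strong support; the bar must never rise with shrinking m
        # beyond that, or a true length could be rejected while its chance
        # one-base extension qualifies
        needed = support_frac if m >= 4 else max(support_frac, 0.75)
        if len(hits) < needed * n:
            continue
        if use_decoy:
            null = sum(1 for d in decoys
                       if _best_match(d, m, max_shift, max_borrow) is not None)
            if len(hits) / n - null / len(decoys) < excess_frac:
                continue
        candidates.append((m, hits))
    def _borrow_artifact(m, hits):
        """A longer candidate whose extension exists only by borrowing
        element terminal bases is an artifact: the borrowed characters are
        then the same element bases for every copy matched at that shift,
        whereas a genuinely longer duplication varies from site to site.
        (When termini overshot and absorbed the duplication, borrowed
        characters are each copy's own target bases and vary, so those
        candidates survive.) Supporters are grouped by shift; a group is
        artifact-like when its borrowed characters are near-constant."""
        n_sup = len(hits)
        groups: dict[tuple[int, int], list] = {}
        for copy, ((dl, dr), lx, rx) in hits:
            groups.setdefault((dl, dr), []).append((lx, rx))
        artifact_cover = 0
        for (dl, dr), members in groups.items():
            if dl <= 0 and dr >= 0:
                continue  # pure trims cannot borrow element bases
            if len(members) < 3:
                artifact_cover += len(members)  # too small to judge; suspect
                continue
            constant = True
            if dl > 0:
                for p in range(1, dl + 1):
                    cnt = Counter(lx[-p] for lx, _ in members)
                    if max(cnt.values()) < 0.6 * len(members):
                        constant = False
            if dr < 0:
                for p in range(-dr):
                    cnt = Counter(rx[p] for _, rx in members)
                    if max(cnt.values()) < 0.6 * len(members):
                        constant = False
            if constant:
                artifact_cover += len(members)
        return artifact_cover >= 0.5 * n_sup

    consensus_len = 0
    supporters: list = []
    if candidates:
        best_support = max(len(h) for _, h in candidates)
        plateau = [(m, h) for m, h in candidates if len(h) >= 0.75 * best_support]
        for i, (m, hits) in enumerate(plateau):  # m descending
            if i < len(plateau) - 1 and _borrow_artifact(m, hits):
                continue
            consensus_len = m
            supporters = hits
            break
    calls = []
    supported = {id(copy): f for copy, f in supporters}
    for copy in uniq:
        f = supported.get(id(copy))
        if f is not None:
            (dl, dr), lx, rx = f
            calls.append(TSDCall(left=lx[-consensus_len:],
                                 right=rx[:consensus_len],
                                 length=consensus_len, shift=(dl, dr),
                                 left_flank=lx, right_flank=rx))
        else:
            lx, rx = _flanks_at(copy, 0, 0)
            m = _longest_suffix_prefix(lx, rx, min_len, max_len)
            calls.append(TSDCall(left=lx[-m:] if m else "",
                                 right=rx[:m] if m else "", length=m,
                                 left_flank=lx, right_flank=rx))
    if consensus_len == 0:
        return TSDReport(calls=calls, consensus_length=0, motif="")
    winners = [c.left for c in calls if c.length == consensus_len]
    motif = _iupac_observed(winners)
    return TSDReport(calls=calls, consensus_length=consensus_len, motif=motif)


def fit_target_site_model(tsd: TSDReport,
                          copies_with_flanks: list[tuple[str, str, str]],
                          context: int = 2) -> TargetSiteModel | None:
    """Reconstruct the pre-insertion target pattern around the TSD.

    Extends the TSD motif with up to `context` flanking positions (before
    the left TSD copy, after the right one). Only the run of conserved
    positions (a single-base majority call) adjacent to the core is kept:
    a Tc4-style family yields ``C|TNA|G`` while random context degenerates
    to the core alone. Returns None when there is no consensus TSD.
    """
    k = tsd.consensus_length
    if k < 1:
        return None
    lefts, rights = [], []
    for call in tsd.calls:
        if call.length != k:
            continue
        lx, rx = call.left_flank, call.right_flank
        if len(lx) >= k + context and len(rx) >= k + context:
            lefts.append(lx[-(k + context):-k])
            rights.append(rx[k:k + context])

    def conserved_run(cols: list[str], from_right: bool) -> str:
        """Run of strongly conserved positions (one base at >=80%)
        adjacent to the core."""
        kept = []
        idx = range(len(cols[0]) - 1, -1, -1) if from_right else range(len(cols[0]))
        for p in idx:
            counts = Counter(s[p] for s in cols)
            base, cnt = counts.most_common(1)[0]
            if base not in "ACGT" or cnt < 0.8 * len(cols):
                break
            kept.append(base)
        return "".join(reversed(kept)) if from_right else "".join(kept)

    if lefts:
        lctx = conserved_run(lefts, from_right=True)
        rctx = conserved_run(rights, from_right=False)
    else:
        lctx = rctx = ""
    return TargetSiteModel(pattern=f"{lctx}{tsd.motif}{rctx}", core=tsd.motif,
                           annotated=f"{lctx}|{tsd.motif}|{rctx}")


# --------------------------------------------------------------- logos

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def _logo(rows: list[str], window: str) -> PositionLogo:
    n_pos = len(rows[0])
    counts = np.zeros((n_pos, 4))
    for s in rows:
        for p, ch in enumerate(s):
            i = _BASE_IDX.get(ch)
            if i is not None:
                counts[p, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts),
                      where=totals > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = np.where(totals[:, 0] > 0, 2.0 + plogp.sum(axis=1), 0.0)
    return PositionLogo(window=window, freqs=freqs, ic=ic, n_seqs=len(rows))


def boundary_logo(copies_with_flanks: list[tuple[str, str, str]],
                  tir: TIRReport | None = None, upstream: int = 15,
                  downstream: int = 11) -> tuple[PositionLogo, PositionLogo]:
    """Sequence logos of the element boundaries.

    The 5' logo covers the `upstream` positions immediately before the 5'
    terminus and the 3' logo the `downstream` positions after the 3'
    terminus; with a TIR report the windows anchor at the outermost TIR
    base. Copies with short flanks are excluded with a warning.
    """
    rows5, rows3 = [], []
    skipped = 0
    for left, elem, right in copies_with_flanks:
        if tir is not None:
            left = left + elem[:tir.five[0]]
            right = elem[tir.three[1]:] + right
        if len(left) < upstream or len(right) < downstream:
            skipped += 1
            continue
        rows5.append(left[-upstream:])
        rows3.append(right[:downstream])
    if skipped:
        warnings.warn(f"{skipped} copies excluded from logo (flank too short)")
    if not rows5:
        raise ValueError("no copies with sufficient flanks for logo")
    return (_logo(rows5, f"-{upstream}..-1 of 5' terminus"),
            _logo(rows3, f"+1..+{downstream} of 3' terminus"))


def hallmark_report(element: str,
                    copies_with_flanks: list[tuple[str, str, str]] | None = None,
                    **tsd_kwargs) -> HallmarkReport:
    """Convenience wrapper: run all detectors on one curated element."""
    report = HallmarkReport()
    report.tir = find_tir(element)
    report.ltr = find_ltr(element)
    if copies_with_flanks and len(copies_with_flanks) >= 3:
        report.tsd = find_tsd(copies_with_flanks, **tsd_kwargs)
        report.target_site_model = fit_target_site_model(
            report.tsd, copies_with_flanks)
    elif copies_with_flanks:
        report.notes.append("fewer than 3 copies; no TSD consensus call")
    return report
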