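# Methods

`tecurate` implements the alignment-based manual-curation workflow for
transposable-element (TE) consensus libraries as a reproducible, scriptable
pipeline, together with the annotation statistics usually computed from the
resulting libraries and a simulator that makes the whole chain testable
against known truth.

## The curation model

A draft consensus (typically an automatically assembled repeat-family
representative) is refined by examining its genomic copies:

1. **Mine** — locate copies of the draft in the genome. The internal
   search is a seed-and-extend local aligner: exact k-mer seeds (k = 11)
   clustered by diagonal, each cluster resolved by a Smith–Waterman
   alignment with affine gaps (match +1, mismatch −2, gap open −5, gap
   extend −1). A precomputed 12-column hit table can be supplied instead.
2. **Select and extend** — the best 20 hits by score are kept (ties broken
   by alignment length, then coordinates, so selection is deterministic)
   and extended by 2 kb of flanking sequence on both sides, so that the
   true element termini and the insertion-site context fall inside the
   alignment. Hits whose genomic span overlaps a higher-scoring hit by
   more than half of the shorter span are culled first: fragmented search
   output otherwise yields several intervals of one locus, and their
   identical rows would masquerade as conserved sequence downstream.
3. **Align** — each extended, orientation-normalized copy is aligned
   pairwise to the current consensus (global with cost-free terminal gaps,
   which tolerates both flanking DNA and truncated copies) and the
   alignments are projected onto shared anchor columns (a star alignment).
   Copy-only residues become anchor-gap insertion blocks. Blocks wider
   than 24 columns at the alignment boundaries — flanks, and any element
   sequence a truncated draft does not cover — are merged by a one-level
   mini star alignment anchored on the median-length inserted segment,
   using anchored-extension alignment from the shared junction;
   sub-threshold segments (raw score < 18) are kept unaligned so that
   chance matches between random flanks cannot fabricate conserved
   columns.
4. **Call the consensus** — per column, the majority rule with IUPAC
   ambiguity codes; per indel region, indel lengths treated as independent
   events; complex regions replaced by a fixed 10-N placeholder; termini
   found where the alignment stops being deep and consistent (below).
5. **Iterate and polish** — the loop is re-run with the improved
   consensus as the anchor (`tecurate.pipeline.curate_from_genome`,
   default two rounds, stopping early on convergence). One pass recovers
   sequence missing from a truncated draft, but that sequence enters
   through insertion blocks whose per-copy alignment is less precise than
   anchored columns; the second pass aligns every copy against a
   full-length anchor. Per-copy element/flank junctions are then
   re-derived by aligning the finished consensus back onto each raw copy,
   with each junction pinned by locally re-placing the consensus's
   terminal 20-mer (plain global end placement is ambiguous by a base or
   two wherever terminal characters mismatch). Finally, because pairwise
   alignment cannot anchor a residual element stretch shorter than its
   alignability threshold (a diverged ~15 bp tail scores below any safe
   cutoff against a single copy), the consensus is extended by a majority
   walk over the stacked per-copy flanks: a naive column majority serves
   as reference, each copy adopts the ±2 bp junction offset that best
   matches it, and the consensus grows while a clear majority (≥ 60% of
   ≥ 60% of copies) agree — element columns at 8% divergence agree at
   ~0.85–0.95, truly flanking columns at ~0.25–0.5, so the walk stops at
   the boundary; a rare one-base over-extension is recoverable by the TSD
   search's borrow adjustment.

## Consensus rules

With `n` rows at a column (end gaps outside a row's aligned span are
ignored, and the anchor row never votes):

* gap wins if gaps exceed half of all rows;
* otherwise the most frequent base wins if its frequency among non-gap
  rows strictly exceeds `majority_frac` (default 0.5);
* otherwise the IUPAC code of all bases at frequency ≥ `minor_frac`
  (default 0.25); `N` when no base qualifies.

Indel regions are maximal column runs where at least `gap_region_frac`
(default 0.25) of the spanning rows gap. Sparser gaps are left to the
column rule (which resolves them identically); the threshold exists
because at realistic depth, single-copy indels are frequent enough that
literally any column with one gap would chain unrelated events into one
giant region. Within a region, rows are grouped by how many residues they
place there; the plurality length class wins, ties resolve toward the
shorter (deletion-favoring) variant, and the kept columns are filled by
the column rule over the winning rows. A region with more than
`max_length_classes` (4) distinct lengths, or where no class reaches
`complexity_frac` (⅓) of the rows, is deemed unresolvable and receives
exactly `NNNNNNNNNN` — ten placeholder Ns regardless of region width.

## Termini ("the alignable part")

A sliding 15-column window scans inward from each end of the alignment;
the element begins at the first window whose mean depth reaches both an
absolute floor (`min_depth`, 3) and `depth_frac` (0.5) of the copies, and
whose mean top-base agreement reaches `agreement_min` (0.7) — refined to
the first qualifying column, then extended outward under relaxed
thresholds (0.8× both), tolerating at most two consecutive ragged columns.
Columns below the depth floor contribute zero agreement: a near-empty
column is trivially self-consistent and must not prop up a window mean.
The relative-depth requirement is what separates the element from pockets
of coincidentally shared flank (e.g. where extended intervals of
neighboring insertions overlap).

## Hallmarks

**TIRs / LTRs.** Local alignment of the 5′ terminal region against the
reverse complement (TIR) or the plain sequence (LTR) of the 3′ terminal
region; reported when long enough (8 bp / 80 bp), clean enough (mismatch
fraction ≤ 0.2 / identity ≥ 0.8) and anchored near the termini (within
30 / 50 bp). Empirical false-positive rates on random 1 kb sequences are
≤ 5% at defaults.

**TSDs.** The target site duplication is the longest flank suffix/prefix
duplication supported by the copies. Detected termini carry a few bp of
per-copy error, so each copy may match a candidate length under a small
boundary adjustment: trimming flank bases back out of the element (up to
10 bp) or borrowing element bases back into the flank (up to 6 bp), with
the allowed range shrinking for short candidates. The consensus length is
the longest `m` matched by enough copies (≥ 50% for m ≥ 6, ≥ 60% for
m = 4–5, ≥ 75% for m ≤ 3 — shorter candidates are cheap to match by
chance and a real short TSD is matched by essentially every copy), with
three further guards, each of which exists because the adjustment freedom
otherwise accumulates chance matches:

* *decoy calibration* — the same search run on junctions taken 12 bp
  further out in the flanks (where no duplication exists) must score
  clearly lower (support excess ≥ 0.25);
* *support plateau* — support is near-constant for every length up to the
  true one and cliffs just above it, so the called length must retain
  ≥ 75% of the best support among qualifying lengths;
* *borrow-artifact rejection* — when an element's terminal base happens to
  match the insertion-site context, a one-base-longer "duplication" exists
  at every copy; such extensions are recognized because the borrowed
  characters are the same element bases across supporters, whereas a
  genuinely longer duplication varies from site to site.

One internal mismatch is tolerated for duplications ≥ 8 bp, at the
unshifted boundary only. Copies at identical loci are collapsed first.

**Target-site models.** The TSD motif is the IUPAC code of the bases
observed per position (a motif like `TNA` means "any base was seen here").
The pre-insertion target is reconstructed by extending the motif with
strongly conserved context positions (one base at ≥ 80% frequency)
adjacent to the core, annotated as `left|core|right` — for a Tc4-style
family inserting into the interrupted palindrome CTNAG and duplicating
only the central trinucleotide, this yields `C|TNA|G`.

**Boundary logos.** Per-position base frequencies and information content
(2 + Σ f·log₂ f bits) over fixed windows before the 5′ and after the 3′
terminus (defaults 15 and 11 bp), anchored at the outermost TIR base when
a TIR is known. No small-sample IC correction is applied; with few copies
the expected IC of random sequence is positive by roughly 3/(2·ln 2·N)
bits per position.

## Classification and nomenclature

Labels follow the `Class/Superfamily` convention of the masking tool
chain; the validator checks tokens against a seeded, extensible vocabulary
and suggests the nearest valid token (case-insensitive match first, then
edit distance ≤ 2), because silent misspellings break downstream scripts.
Rule-based classification takes homology first (best subject with e-value
≤ 1e-5 covering ≥ 50% of the consensus adopts its classification), then
structure (TIR + TSD → `DNA/Unknown`; LTR pair → `LTR/Unknown`; structure
alone never assigns a superfamily), else `Unknown`; every decision is
recorded in a replayable trace, and homology/structure conflicts are noted
with homology winning.

Library comparison implements the 80-80-80 family rule — a pair qualifies
when ≥ 80 bp align at ≥ 80% identity covering ≥ 80% of the shorter
sequence — and a 95-80-98 subfamily preset interpreted by analogy as
(identity ≥ 95%, coverage ≥ 80%, span ≥ 98 bp); both are overridable, and
the subfamily preset should be treated as an interpretation rather than a
canonical definition. Fragmented alignments are summed: hits are kept
greedily by score while non-overlapping on the shorter sequence, identity
is span-weighted, and coverage is the union of kept fragments.

## Annotation statistics

The Kimura 2-parameter distance corrects observed transition (p) and
transversion (q) proportions for multiple hits:
K = −½·ln(1 − 2p − q) − ¼·ln(1 − 2q), undefined (an error) at saturation.
Divergence defaults to the `pct_div` column of the `.out` table;
recomputation from alignment rows counts transitions A↔G and C↔T over
columns where both rows hold unambiguous bases. No CpG adjustment is
applied.

Repeat landscapes bin each annotated interval's full span into half-open
1%-divergence bins per top-level category, pooling ≥ 49% into the last
bin; overlaps are deliberately not flattened (standard landscape
semantics), so cells sum to total masked bp. The per-category masked
summary *does* flatten overlaps — each base counts once, attributed to the
highest-scoring annotation covering it — so percentages cannot exceed 100.
The activity filter flags a subfamily as putatively active when at least
`min_copies` (10) of its annotated copies lie at divergence ≤ `max_div`
(0.0 exactly by default; an epsilon is configurable because rounding
conventions differ between producers of `.out` tables).

## Peer review and versioning

Each consensus moves raw → curated → in_review → accepted/returned
(returned → curated re-enters the loop); acceptance requires a reviewer
distinct from the curator. Every event appends a SHA-256 hash-chained
entry to a TSV ledger, so tampering or reordering is detectable, and every
new consensus version is added to the family alignment file as an
`id.vN` row next to the older versions. Reviewer assignment supports a
seeded random derangement among curators or a fixed round-robin panel.

## Simulator

The simulator implants decayed copies of randomly generated elements
(with planted TIR or LTR structure) into a uniform-random background.
Insertions duplicate host bases at the insertion point, or only the
marked core of an IUPAC target pattern (`C[TNA]G`); sites keep ≥ 4.5 kb
spacing so each copy's 2 kb flanks stay copy-specific. Copies decay under
a two-rate substitution process — `divergence` d is the expected per-site
substituted proportion, transitions at d·κ/(κ+1) and transversions at
d/(κ+1) with κ = 2 by default — so `kimura2p` applied to those target
proportions is the closed-loop expectation for parameter-recovery tests.
Small indels occur at 0.1× the substitution rate with geometric lengths
(mean 2); 10% of copies are 5′-truncated by a uniform 10–50% by default.
Everything is bit-deterministic under the seed.

What the simulator does **not** emulate: genome base composition and
isochore/GC structure, low-complexity and satellite context around
insertion sites, nested insertions, element subfamily structure or
age-stratified waves (beyond running several specs), and TSD mutation
after insertion. Passing tests therefore demonstrate correctness of the
algorithms under clean insertion models, not performance on real
heterochromatin.

## Problem sizes and numerics

The recovery studies use 800 bp elements with 15 copies at 8% divergence
in 120 kb genomes, 50 families per study, which keeps a full study in the
low minutes on one core while leaving each stage statistically
informative. Alignment DP kernels are exact (no banding); scores are
integers; all thresholds above are keyword arguments with the quoted
defaults. Ties in hit ranking, indel-length classes and TSD candidate
lengths resolve deterministically as described, so identical inputs give
identical outputs.

## Known limitations

* Termini are recovered to within a few bp, not exactly; families whose
  flanks contain repetitive or shared sequence can still gain or lose a
  few terminal columns (the TSD search compensates within ±10 bp).
* The TSD statistic assumes most copies kept their duplication intact;
  heavily decayed families (few intact junctions) fall below the support
  thresholds and are reported as having no consensus TSD rather than a
  guessed one.
* Structural classification is conservative by design (class-level only);
  superfamily assignment requires homology evidence, which this package
  ingests but does not generate.
* The internal search aligner is meant for desk-scale genomes (up to a
  few Mb); for full assemblies, import hits from a dedicated search tool.
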