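# tecurate

**Curation toolkit for transposable-element consensus libraries.**

Automated repeat-discovery tools hand you draft consensus sequences that
are often truncated, chimeric or unclassifiable — especially in taxa far
from any curated repeat database, where most families come out labelled
"Unknown". Turning such drafts into a usable TE library is traditionally
months of manual work: align the genomic copies of each consensus, find
the element's true termini, fix ambiguous bases, look for the structural
hallmarks that prove mobility (terminal inverted repeats, long terminal
repeats, target site duplications), classify, and have someone else
review the call. `tecurate` packages that workflow — the
"Blast-Extend-Extract" loop and everything downstream of it — as a
scriptable, testable pipeline for curators, with a simulator that
generates genomes with implanted TE families so every stage can be
validated against known truth.

## What it does

* **Copy mining** — seed-and-extend search of a draft consensus against a
  genome (or import of a 12-column hit table), selection of the best 20
  hits, 2 kb flank extension, strand-normalized extraction.
* **Consensus refinement** — star multiple alignment anchored on the
  current consensus; majority-rule IUPAC consensus with
  insertion/deletion lengths treated as independent events, 10-N
  placeholders for unresolvable regions, and detection of the "alignable
  part" (the element proper) among the flanks. The loop iterates until
  the consensus converges.
* **Hallmark detection** — TIRs, LTRs, per-copy target site duplications
  with a consensus length/motif call, reconstructed pre-insertion target
  models (e.g. the Tc4-style `C|TNA|G` interrupted palindome cut), and
  boundary sequence logos.
* **Classification** — rule-based (homology evidence first, structure
  second) with replayable decision traces, RepeatMasker-style
  `Class/Superfamily` nomenclature validation with suggestions, library
  renaming, and library comparison under the 80-80-80 family /
  95-80-98 subfamily rules.
* **Annotation statistics** — Kimura 2-parameter divergence
  (K = −½ln(1−2p−q) − ¼ln(1−2q)), repeat landscapes, per-category masked
  fractions from `.out` tables, and the putatively-active-subfamily
  filter (≥ 10 copies at 0% divergence).
* **Peer review** — a hash-chained TSV ledger implementing the
  raw → curated → in_review → accepted/returned state machine, with
  consensus versions accumulated inside the family alignment files.
* **Simulation** — genomes with implanted families under controlled copy
  number, divergence (two-rate substitution process), truncation,
  TIR/LTR/TSD structure and target-site patterns, with truth tables in
  BED-like and `.out` projections.

See `docs/methods.md` for the model, the consensus rules, all tunable
parameters and the known limitations.

## Worked example

Simulate a genome with one implanted DNA-transposon family, then curate
it starting from a deliberately truncated, noisy draft:

```python
import numpy as np
from tecurate import (FamilySpec, simulate_genome, make_raw_consensus,
                      ConsensusRecord)
from tecurate.pipeline import curate_from_genome

fam = FamilySpec(name="famA", length=800, classification="DNA/hAT",
                 tir_len=12, tsd_len=5, copy_number=15,
                 divergence=0.08, truncation_prob=0.1)
sim = simulate_genome([fam], background_len=120_000, seed=7)

rng = np.random.default_rng(7)
raw = ConsensusRecord(id="famA",
                      sequence=make_raw_consensus(sim.elements["famA"], rng))
out = curate_from_genome(raw, sim.contigs)

rec, hm = out.curation.record, out.hallmarks
print(f"draft {len(raw)} bp -> curated {len(rec)} bp "
      f"(true element {len(sim.elements['famA'])} bp)")
print(f"TIR: arms {hm.tir.five}/{hm.tir.three}, "
      f"{hm.tir.mismatches} mismatches")
print(f"TSD: length {hm.tsd.consensus_length}, motif {hm.tsd.motif}")
```

prints

```
draft 560 bp -> curated 800 bp (true element 800 bp)
TIR: arms (0, 12)/(788, 800), 0 mismatches
TSD: length 5, motif NNNNN
```

The 560 bp draft (the true element cut to 70% with 2% noise, emulating an
automated consensus) is extended back to essentially full length; the
12 bp terminal inverted repeats are recovered at both ends, and the 5 bp
target site duplication is called at its exact length (its motif is
`NNNNN` because this family inserts without sequence preference — every
base occurs at every TSD position). A Tc4-style family simulated with
`target_site_pattern="C[TNA]G"` instead yields motif `TNA` and the
reconstructed cut `C|TNA|G`.

The same pipeline is available from the shell:

```bash
tecurate simulate --spec families.yaml --seed 7 --out g.fa --truth truth.tsv
tecurate curate --anchor draft.fa --genome g.fa --out curated.fa --msa-out fam.aln.fa
tecurate landscape --rm-out genome.out --genome-size 120000 --out-table land.tsv
tecurate active --rm-out genome.out --min-copies 10 --max-div 0
```

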