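import numpy as np
import pytest

from tecurate._dna import matches_iupac, revcomp
from tecurate.annotation_stats import active_subfamilies, kimura2p, landscape
from tecurate.hallmarks import find_ltr, find_tir
from tecurate.seqio import read_rm_out, write_rm_out
from tecurate.simulator import (
    FamilySpec, make_raw_consensus, mutate_copy, parse_target_pattern,
    project_truth_to_out, simulate_family, simulate_genome,
)


class TestFamilySpec:
    def test_tir_and_ltr_mutually_exclusive(self):
        with pytest.raises(ValueError):
            FamilySpec(name="x", tir_len=10, ltr_len=100)

    def test_pattern_core_must_match_tsd_len(self):
        with pytest.raises(ValueError):
            FamilySpec(name="x", target_site_pattern="C[TNA]G", tsd_len=5)

    def test_pattern_parsing(self):
        assert parse_target_pattern("C[TNA]G") == ("C", "TNA", "G")
        with pytest.raises(ValueError):
            parse_target_pattern("CTNAG")


class TestSimulateFamily:
    def test_planted_tir_recovered(self):
        spec = FamilySpec(name="f", length=500, tir_len=10, seed=1)
        elem = simulate_family(spec)
        tir = find_tir(elem)
        assert tir is not None
        assert tir.five[0] == 0 and tir.three[1] == len(elem)

    def test_planted_ltr_identity_one(self):
        spec = FamilySpec(name="f", length=1000, ltr_len=150, seed=2)
        elem = simulate_family(spec)
        ltr = find_ltr(elem)
        assert ltr is not None and ltr.identity == 1.0

    def test_deterministic_under_seed(self):
        spec = FamilySpec(name="f", length=300, tir_len=8, seed=9)
        assert simulate_family(spec) == simulate_family(spec)


class TestSimulateGenome:
    def test_bit_deterministic(self):
        fam = FamilySpec(name="f", length=400, tsd_len=4, copy_number=5,
                         divergence=0.05)
        a = simulate_genome([fam], background_len=50_000, seed=11)
        b = simulate_genome([fam], background_len=50_000, seed=11)
        assert a.contigs == b.contigs
        assert a.truth == b.truth

    def test_zero_divergence_copies_identical(self):
        fam = FamilySpec(name="f", length=400, copy_number=10, divergence=0.0,
                         truncation_prob=0.0, tsd_len=0)
        sim = simulate_genome([fam], background_len=80_000, seed=3)
        g = sim.contigs["ctg1"]
        for t in sim.truth:
            seq = g[t.start:t.end]
            if t.strand == "-":
                seq = revcomp(seq)
            assert seq == sim.elements["f"]
            assert t.divergence == 0.0

    def test_tsd_duplicated_at_both_sides(self):
        fam = FamilySpec(name="f", length=400, tsd_len=6, copy_number=8,
                         divergence=0.0, truncation_prob=0.0)
        sim = simulate_genome([fam], background_len=70_000, seed=5)
        g = sim.contigs["ctg1"]
        for t in sim.truth:
            assert g[t.start - 6:t.start] == t.tsd
            assert g[t.end:t.end + 6] == t.tsd

    def test_tc4_pattern_truth(self):
        fam = FamilySpec(name="tc4", length=500, tir_len=10, tsd_len=3,
                         target_site_pattern="C[TNA]G", copy_number=10,
                         divergence=0.0, truncation_prob=0.0)
        sim = simulate_genome([fam], background_len=100_000, seed=4)
        g = sim.contigs["ctg1"]
        for t in sim.truth:
            assert len(t.tsd) == 3
            assert all(matches_iupac(b, c) for b, c in zip(t.tsd, "TNA"))
            # pre-insertion context reconstructs C TNA G
            assert g[t.start - 4] == "C"
            assert g[t.end + 3] == "G"

    def test_mean_divergence_within_three_se(self):
        fam = FamilySpec(name="f", length=1000, copy_number=20,
                         divergence=0.08, truncation_prob=0.0,
                         indel_factor=0.0)
        divs = []
        for seed in range(5):
            sim = simulate_genome([fam], background_len=150_000, seed=seed)
            divs += [t.divergence for t in sim.truth]
        se = np.std(divs, ddof=1) / np.sqrt(len(divs))
        assert abs(np.mean(divs) - 0.08) <= 3 * se + 1e-9

    def test_impossible_placement_rejected(self):
        fam = FamilySpec(name="f", length=400, copy_number=50)
        with pytest.raises(ValueError):
            simulate_genome([fam], background_len=20_000, seed=0)


class TestMutateCopy:
    def test_transition_bias(self, rng):
        elem = "A" * 20_000
        mut = mutate_copy(elem, 0.2, 2.0, rng)
        # with kappa=2, two thirds of substitutions are transitions
        frac_ts = mut.n_transitions / (mut.n_transitions + mut.n_transversions)
        assert abs(frac_ts - 2 / 3) < 0.05

    def test_k2p_closed_loop(self, rng):
        elem = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
        mut = mutate_copy(elem, 0.1, 2.0, rng)
        expected = kimura2p(0.1 * 2 / 3, 0.1 / 3)
        assert kimura2p(mut.p, mut.q) == pytest.approx(expected, rel=0.05)


class TestTruthProjection:
    def _sim(self):
        fams = [
            FamilySpec(name="hot", length=400, copy_number=12, divergence=0.0,
                       truncation_prob=0.0, classification="DNA/hAT"),
            FamilySpec(name="old", length=400, copy_number=8, divergence=0.1,
                       truncation_prob=0.0, classification="LINE/L1"),
        ]
        return simulate_genome(fams, background_len=150_000, seed=6)

    def test_round_trip_through_out_dialect(self, tmp_path):
        sim = self._sim()
        rows = project_truth_to_out(sim)
        p = tmp_path / "truth.out"
        write_rm_out(rows, p)
        assert read_rm_out(p) == rows

    def test_zero_divergence_row(self):
        sim = self._sim()
        rows = project_truth_to_out(sim)
        hot = [r for r in rows if r.repeat_name == "hot"]
        assert all(r.pct_div == 0.0 for r in hot)

    def test_active_filter_cross_module(self):
        sim = self._sim()
        rows = project_truth_to_out(sim)
        out = active_subfamilies(rows, min_copies=10, max_div=0.0)
        assert list(out.index) == ["DNA"]
        assert out.loc["DNA", "subfamilies"] == "hot"

    def test_landscape_on_projection_matches_bruteforce(self):
        sim = self._sim()
        rows = project_truth_to_out(sim)
        genome_size = len(sim.contigs["ctg1"])
        mat = landscape(rows, genome_size)
        brute = {}
        for r in rows:
            key = (r.category, float(min(int(r.pct_div), 49)))
            brute[key] = brute.get(key, 0) + r.span
        for (cat, b), bp in brute.items():
            assert mat.table.loc[cat, b] == bp


class TestRawConsensus:
    def test_fragment_of_element(self, rng):
        elem = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        raw = make_raw_consensus(elem, rng, keep_frac=0.7, divergence=0.0)
        assert raw == elem[:700]

    def test_noise_applied(self, rng):
        elem = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        raw = make_raw_consensus(elem, rng, keep_frac=1.0, divergence=0.05)
        mism = sum(a != b for a, b in zip(raw, elem))
        assert 0.02 < mism / len(elem) < 0.09
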