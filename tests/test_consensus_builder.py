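from fractions import Fraction
from itertools import combinations_with_replacement

import numpy as np
import pytest

from tecurate.align import align
from tecurate.consensus_builder import (
    MSA, build_star_msa, column_consensus, consensus_from_msa, curate,
    detect_termini, indel_consensus, length_comparison, unresolved_placeholder,
)
from tecurate.seqio import ConsensusRecord
from tecurate.simulator import FamilySpec, make_raw_consensus, mutate_copy

from conftest import rand_seq
from oracles import all_profiles, oracle_column, oracle_indel, region_msa


class TestColumnConsensus:
    def test_clear_majority(self):
        assert column_consensus({"A": 3, "G": 1}) == "A"

    def test_even_tie_gives_ambiguity_code(self):
        assert column_consensus({"A": 2, "G": 2}) == "R"

    def test_four_way_split_gives_n(self):
        assert column_consensus({"A": 1, "C": 1, "G": 1, "T": 1}) == "N"

    def test_gap_majority_wins(self):
        assert column_consensus({"A": 2, "-": 5}) == "-"

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            column_consensus({})

    def test_matches_bruteforce_on_all_small_profiles(self):
        for profile in all_profiles(6):
            assert column_consensus(profile) == oracle_column(profile), profile


class TestIndelConsensus:
    @pytest.mark.parametrize("counts,expected", [
        ([0] * 6 + [5] * 2, 0),          # deletion wins by plurality
        ([3] * 4 + [0] * 3, 3),          # insertion wins by plurality
        ([2] * 3 + [4] * 3, 2),          # tie resolved to the shorter
    ])
    def test_plurality_examples(self, counts, expected):
        msa, region = region_msa(counts)
        assert indel_consensus(msa, region).kept_length == expected

    def test_complex_region_gets_ten_n_placeholder(self):
        msa, region = region_msa([0, 2, 4, 7, 11])
        res = indel_consensus(msa, region)
        assert res.is_placeholder and res.sequence == "N" * 10
        assert unresolved_placeholder(msa, region) == "N" * 10

    def test_plurality_reaching_third_resolves(self):
        msa, region = region_msa([3, 3, 3, 0, 1, 2])
        res = indel_consensus(msa, region)
        assert not res.is_placeholder and res.kept_length == 3

    def test_agreeing_rows_never_get_placeholder(self):
        msa, region = region_msa([4] * 6)
        assert unresolved_placeholder(msa, region) is None

    def test_matches_bruteforce_on_all_small_regions(self):
        for depth in range(1, 7):
            for counts in combinations_with_replacement(range(7), depth):
                if max(counts) == 0:
                    continue
                msa, region = region_msa(list(counts))
                got = indel_consensus(msa, region)
                want = oracle_indel(list(counts))
                if want == "placeholder":
                    assert got.is_placeholder, counts
                    assert got.sequence == "N" * 10
                else:
                    assert not got.is_placeholder and got.kept_length == want, counts


class TestBuildStarMsa:
    def test_identical_copies_no_gaps(self):
        anchor = ConsensusRecord(id="a", sequence="ACGTACGT")
        msa = build_star_msa(anchor, [("c1", "ACGTACGT"), ("c2", "ACGTACGT")])
        assert msa.ncols == 8
        assert all("-" not in row for _, row in msa.rows)

    def test_single_insertion_makes_anchor_gap_columns(self, rng):
        anchor_seq = rand_seq(rng, 50)
        copy = anchor_seq[:25] + "GGG" + anchor_seq[25:]
        msa = build_star_msa(("a", anchor_seq), [("c", copy)])
        assert msa.ncols == 53
        assert msa.rows[0][1].count("-") == 3

    def test_empty_copy_set_rejected(self):
        with pytest.raises(ValueError):
            build_star_msa(("a", "ACGT"), [])

    def test_identity_to_anchor_tracks_divergence(self, rng):
        anchor_seq = rand_seq(rng, 500)
        copies = []
        for i in range(10):
            mut = mutate_copy(anchor_seq, 0.05, 2.0, rng)
            copies.append((f"c{i}", mut.seq))
        msa = build_star_msa(("a", anchor_seq), copies)
        anchor_row = msa.rows[0][1]
        idents = []
        for _, row in msa.rows[1:]:
            pairs = [(x, y) for x, y in zip(anchor_row, row)
                     if x != "-" and y != "-"]
            idents.append(sum(x == y for x, y in pairs) / len(pairs))
        assert 0.93 <= np.mean(idents) <= 0.97


class TestDetectTermini:
    def test_identical_full_length_rows_span_everything(self):
        rows = [("a", "ACGTACGTACGTACGTACGT")] * 5
        msa = MSA(rows=[(f"r{i}", s) for i, (_, s) in enumerate(rows)])
        assert detect_termini(msa) == (0, 20)

    def test_depth_two_alignment_rejected(self):
        msa = MSA(rows=[("a", "ACGTACGT"), ("b", "ACGTACGT")])
        with pytest.raises(ValueError, match="no alignable core"):
            detect_termini(msa, min_depth=3)

    def test_core_found_among_random_flanks(self, rng):
        core = rand_seq(rng, 300)
        copies = [(f"c{i}", rand_seq(rng, 300) + core + rand_seq(rng, 300))
                  for i in range(10)]
        msa = build_star_msa(("a", core), copies)
        start, end = detect_termini(msa)
        anchor_cols = [j for j, ch in enumerate(msa.rows[0][1]) if ch != "-"]
        assert abs(start - anchor_cols[0]) <= 10
        assert abs(end - 1 - anchor_cols[-1]) <= 10


class TestCurate:
    def test_idempotent_on_perfect_family(self, rng):
        seq = rand_seq(rng, 400)
        anchor = ConsensusRecord(id="fam", sequence=seq, status="raw")
        copies = [(f"c{i}", seq) for i in range(6)]
        result = curate(anchor, copies)
        assert result.record.sequence == seq
        assert result.record.version == 2
        assert result.record.status == "curated"

    def test_version_row_appended_to_msa(self, rng):
        seq = rand_seq(rng, 200)
        anchor = ConsensusRecord(id="fam", sequence=seq)
        result = curate(anchor, [(f"c{i}", seq) for i in range(5)])
        labels = [lab for lab, _ in result.msa.rows]
        assert "fam.v1" in labels and "fam.v2" in labels

    def test_consensus_is_iupac_without_gaps(self, rng):
        seq = rand_seq(rng, 300)
        copies = [(f"c{i}", mutate_copy(seq, 0.08, 2.0, rng,
                                        indel_factor=0.1).seq)
                  for i in range(12)]
        result = curate(ConsensusRecord(id="f", sequence=seq), copies)
        assert set(result.record.sequence) <= set("ACGTRYSWKMBDHVN")
        assert "-" not in result.record.sequence

    def test_truncated_anchor_recovers_full_element(self, rng):
        elem = rand_seq(rng, 500)
        raw = ConsensusRecord(id="f", sequence=make_raw_consensus(elem, rng))
        copies = [(f"c{i}",
                   rand_seq(rng, 150) + mutate_copy(elem, 0.05, 2.0, rng).seq
                   + rand_seq(rng, 150))
                  for i in range(12)]
        result = curate(raw, copies)
        r = align(result.record.sequence, elem, mode="glocal")
        assert (r.b_end - r.b_start) >= 0.95 * len(elem)
        assert len(result.record) > len(raw)


class TestLengthComparison:
    def _lib(self, rng, lengths):
        return [ConsensusRecord(id=f"f{i}", sequence=rand_seq(rng, n))
                for i, n in enumerate(lengths)]

    def test_identical_libraries_zero_delta(self, rng):
        lib = self._lib(rng, [100, 200, 300])
        table, summary = length_comparison(lib, lib)
        assert (table["delta"] == 0).all()
        assert summary["median_delta"] == 0

    def test_extension_delta(self, rng):
        before = self._lib(rng, [500])
        after = [ConsensusRecord(id="f0", sequence=rand_seq(rng, 1500))]
        table, summary = length_comparison(before, after)
        assert table["delta"].iloc[0] == 1000

    def test_unmatched_reported_and_excluded(self, rng):
        before = self._lib(rng, [100, 200])
        after = [ConsensusRecord(id="f0", sequence=rand_seq(rng, 100))]
        with pytest.warns(UserWarning):
            table, summary = length_comparison(before, after)
        assert summary["unmatched"] == ["f1"]
        assert len(table) == 1
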