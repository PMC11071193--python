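import math

import numpy as np
import pytest

from tecurate.annotation_stats import (
    active_subfamilies, divergence_from_pair, kimura2p, landscape,
    masked_summary,
)
from tecurate.seqio import AnnotationRow


def _row(query="ctg1", begin=1, end=100, div=0.0, name="famA",
         cls="DNA/hAT", score=1000.0):
    return AnnotationRow(score=score, pct_div=div, pct_del=0.0, pct_ins=0.0,
                         query=query, qbegin=begin, qend=end,
                         qleft=0, strand="+", repeat_name=name,
                         repeat_classification=cls, rbegin=1,
                         rend=end - begin + 1, rleft=0)


class TestKimura2p:
    def test_zero_divergence(self):
        assert kimura2p(0.0, 0.0) == 0.0

    # expected values frozen from an exact high-precision evaluation of
    # K = -1/2 ln(1-2p-q) - 1/4 ln(1-2q)
    @pytest.mark.parametrize("p,q,expected", [
        (0.10, 0.05, 0.17018116514034704),
        (0.00, 0.15, 0.17042820073357055),
        (0.10, 0.00, 0.11157177565710487),
    ])
    def test_closed_form_values(self, p, q, expected):
        assert kimura2p(p, q) == pytest.approx(expected, abs=1e-12)

    def test_saturated_divergence_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            kimura2p(0.4, 0.3)
        with pytest.raises(ValueError):
            kimura2p(-0.1, 0.0)

    def test_exceeds_raw_distance(self):
        # multiple-hit correction always inflates: K >= p + q
        for p in np.linspace(0, 0.3, 13):
            for q in np.linspace(0, 0.2, 9):
                if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                    continue
                k = kimura2p(p, q)
                assert k >= p + q - 1e-12
                if p + q > 0:
                    assert k > p + q - 1e-9 and k != pytest.approx(0.0)


class TestDivergenceFromPair:
    def test_identical_rows(self):
        est = divergence_from_pair("ACGTACGT", "ACGTACGT")
        assert (est.p, est.q, est.k) == (0.0, 0.0, 0.0)

    def test_ten_transitions_in_hundred(self):
        cons = "A" * 100
        copy = "G" * 10 + "A" * 90  # A->G is a transition
        est = divergence_from_pair(cons, copy)
        assert est.p == 0.1 and est.q == 0.0
        assert est.k == pytest.approx(0.11157177565710487, abs=1e-12)

    def test_ambiguous_and_gap_columns_excluded(self):
        est = divergence_from_pair("ANC-G", "AGCTG")
        assert est.n_sites == 3  # N column and gap column dropped

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            divergence_from_pair("ACGT", "ACG")
        with pytest.raises(ValueError):
            divergence_from_pair("NNNN", "ACGT")


class TestLandscape:
    def test_single_row_binning(self):
        mat = landscape([_row(begin=1, end=100, div=3.4)], genome_size=10_000)
        pct = mat.percent()
        assert pct.loc["DNA", 3.0] == pytest.approx(1.0)
        assert mat.total_bp == 100

    def test_conservation(self, rng):
        rows = [_row(begin=int(b), end=int(b) + int(l) - 1,
                     div=float(d), name=f"f{i % 7}",
                     cls=["DNA/hAT", "LINE/L1", "Unknown"][i % 3])
                for i, (b, l, d) in enumerate(zip(
                    rng.integers(1, 10_000, 300),
                    rng.integers(10, 500, 300),
                    rng.uniform(0, 60, 300)))]
        mat = landscape(rows, genome_size=1_000_000)
        assert mat.total_bp == sum(r.span for r in rows)

    def test_matches_bruteforce_binning(self, rng):
        rows = [_row(begin=1, end=int(l), div=float(d),
                     cls=["DNA/hAT", "LTR/Gypsy", "SINE/tRNA", "Unknown"][i % 4])
                for i, (l, d) in enumerate(zip(rng.integers(10, 1000, 1000),
                                               rng.uniform(0, 55, 1000)))]
        mat = landscape(rows, genome_size=10_000_000)
        # brute force: independent re-binning
        for r in rows:
            pass
        brute = {}
        for r in rows:
            b = min(int(r.pct_div), 49)
            key = (r.category, float(b))
            brute[key] = brute.get(key, 0) + r.span
        for (cat, b), bp in brute.items():
            assert mat.table.loc[cat, b] == bp
        assert mat.total_bp == sum(brute.values())

    def test_negative_divergence_rejected(self):
        row = _row()
        row.pct_div = -1.0
        with pytest.raises(ValueError):
            landscape([row], genome_size=100)


class TestMaskedSummary:
    def test_disjoint_rows_sum(self):
        rows = [_row(begin=1, end=100), _row(begin=501, end=600)]
        out = masked_summary(rows, genome_size=10_000)
        assert out.loc["DNA", "bp"] == 200
        assert out.loc["DNA", "percent"] == pytest.approx(2.0)
        assert out.loc["total", "bp"] == 200

    def test_overlap_resolved_by_score(self):
        rows = [_row(begin=1, end=100, cls="DNA/hAT", score=100),
                _row(begin=1, end=100, cls="LINE/L1", score=50, name="famB")]
        out = masked_summary(rows, genome_size=10_000)
        assert out.loc["DNA", "bp"] == 100
        assert out.loc["LINE", "bp"] == 0
        assert out.loc["total", "bp"] == 100

    def test_partial_overlap_counts_once(self):
        rows = [_row(begin=1, end=100, score=100),
                _row(begin=51, end=150, score=50, name="famB")]
        out = masked_summary(rows, genome_size=1000)
        assert out.loc["total", "bp"] == 150
        assert out.loc["total", "percent"] <= 100

    def test_empty_annotation(self):
        out = masked_summary([], genome_size=1000)
        assert out.loc["total", "bp"] == 0


class TestActiveSubfamilies:
    def test_exactly_ten_copies_at_zero_qualifies(self):
        rows = [_row(name="act", div=0.0, begin=i * 200 + 1, end=i * 200 + 100)
                for i in range(10)]
        out = active_subfamilies(rows)
        assert out.loc["DNA", "n_subfamilies"] == 1

    def test_nine_copies_do_not_qualify(self):
        rows = [_row(name="act", div=0.0) for _ in range(9)]
        rows += [_row(name="act", div=2.1) for _ in range(50)]
        assert len(active_subfamilies(rows)) == 0

    def test_counts_match_bruteforce_on_mixed_fixture(self, rng):
        rows = []
        copy_plan = {}
        for i in range(20):
            name = f"sub{i}"
            cls = ["DNA/hAT", "LTR/Gypsy", "Unknown"][i % 3]
            n_zero = int(rng.integers(0, 20))
            n_old = int(rng.integers(0, 10))
            copy_plan[name] = (cls, n_zero)
            rows += [_row(name=name, cls=cls, div=0.0) for _ in range(n_zero)]
            rows += [_row(name=name, cls=cls, div=float(rng.uniform(1, 30)))
                     for _ in range(n_old)]
        out = active_subfamilies(rows, min_copies=10, max_div=0.0)
        brute = {}
        for name, (cls, n_zero) in copy_plan.items():
            if n_zero >= 10:
                cat = cls.split("/")[0]
                brute[cat] = brute.get(cat, 0) + 1
        got = {cat: int(out.loc[cat, "n_subfamilies"]) for cat in out.index}
        assert got == brute
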