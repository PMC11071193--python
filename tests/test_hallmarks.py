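import numpy as np
import pytest

from tecurate._dna import revcomp
from tecurate.hallmarks import (
    boundary_logo, find_ltr, find_tir, find_tsd, fit_target_site_model,
)
from tecurate.simulator import FamilySpec, simulate_genome

from conftest import rand_seq, truth_flanks


class TestFindTir:
    def test_perfect_terminal_arms(self):
        # poly-A middle blocks chance extension of the arms
        arm = "CAGTGC"
        elem = arm + "A" * 300 + revcomp(arm)
        tir = find_tir(elem, min_len=6)
        assert tir is not None
        assert tir.five == (0, 6) and tir.three == (len(elem) - 6, len(elem))
        assert tir.mismatches == 0

    def test_one_mismatch_in_ten_reported(self):
        arm = "ACGTTGCACG"
        arm_mut = arm[:5] + "C" + arm[6:]  # one internal substitution
        elem = arm + "A" * 300 + revcomp(arm_mut)
        tir = find_tir(elem, min_len=10)
        assert tir is not None and tir.mismatches == 1
        assert tir.length == 10

    def test_random_sequences_rarely_hit(self):
        false_calls = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            if find_tir(rand_seq(r, 1000)) is not None:
                false_calls += 1
        assert false_calls <= 5

    def test_too_short_element(self):
        assert find_tir("ACGTACGTAC", min_len=8) is None


class TestFindLtr:
    def test_identical_terminal_repeats(self, rng):
        ltr = rand_seq(rng, 150)
        elem = ltr + rand_seq(rng, 800) + ltr
        rep = find_ltr(elem)
        assert rep is not None and rep.identity == 1.0
        assert rep.length >= 150

    def test_inverted_repeats_do_not_count(self, rng):
        arm = rand_seq(rng, 150)
        elem = arm + rand_seq(rng, 800) + revcomp(arm)
        assert find_ltr(elem) is None

    def test_diverged_repeats_detected(self, rng):
        ltr = rand_seq(rng, 200)
        noisy = list(ltr)
        for p in rng.choice(200, size=30, replace=False):  # 85% identity
            noisy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[noisy[p]]
        elem = ltr + rand_seq(rng, 700) + "".join(noisy)
        rep = find_ltr(elem, min_identity=0.8)
        assert rep is not None and 0.8 <= rep.identity < 1.0

    def test_random_sequences_rarely_hit(self):
        false_calls = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            if find_ltr(rand_seq(r, 1000)) is not None:
                false_calls += 1
        assert false_calls <= 5


def synthetic_family(rng, tsd, n_copies=8, elem_len=200, flank=40):
    """Copies sharing an element, each with its own flanks and a given TSD."""
    elem = rand_seq(rng, elem_len)
    out = []
    for _ in range(n_copies):
        left = rand_seq(rng, flank - len(tsd)) + tsd
        right = tsd + rand_seq(rng, flank - len(tsd))
        out.append((left, elem, right))
    return out


class TestFindTsd:
    def test_exact_eight_bp_duplication(self, rng):
        fam = synthetic_family(rng, "ACGTACGT")
        rep = find_tsd(fam)
        assert rep.consensus_length == 8
        assert all(c.left == "ACGTACGT" for c in rep.calls if c.length == 8)

    def test_no_duplication_calls_none(self, rng):
        elem = rand_seq(rng, 200)
        fam = [(rand_seq(rng, 40), elem, rand_seq(rng, 40)) for _ in range(8)]
        rep = find_tsd(fam)
        assert rep.consensus_length == 0 and rep.motif == ""

    def test_tna_style_motif(self, rng):
        elem = rand_seq(rng, 200)
        fam = []
        for core in ("TAA", "TCA", "TGA", "TTA"):
            left = rand_seq(rng, 37) + core
            right = core + rand_seq(rng, 37)
            fam.append((left, elem, right))
        rep = find_tsd(fam)
        assert rep.consensus_length == 3
        assert rep.motif == "TNA"

    def test_recall_on_simulated_families(self):
        hits = 0
        n_fams = 20
        for seed in range(n_fams):
            tsd_len = 2 + seed % 9  # lengths 2..10
            fam = FamilySpec(name="f", length=500, tir_len=10,
                             tsd_len=tsd_len, copy_number=10, divergence=0.0,
                             truncation_prob=0.0)
            sim = simulate_genome([fam], background_len=80_000, seed=seed)
            rep = find_tsd(truth_flanks(sim))
            hits += rep.consensus_length == tsd_len
        assert hits >= 0.9 * n_fams


class TestTargetSiteModel:
    def test_tc4_style_site(self):
        fam = FamilySpec(name="tc4", length=600, tir_len=10, tsd_len=3,
                         target_site_pattern="C[TNA]G", copy_number=20,
                         divergence=0.02, truncation_prob=0.0)
        sim = simulate_genome([fam], background_len=180_000, seed=2)
        flanks = truth_flanks(sim)
        rep = find_tsd(flanks)
        assert rep.consensus_length == 3 and rep.motif == "TNA"
        model = fit_target_site_model(rep, flanks)
        assert model.annotated == "C|TNA|G"
        assert model.pattern == "CTNAG"

    def test_random_context_degenerates_to_core(self, rng):
        fam = synthetic_family(rng, "GATC", n_copies=10)
        rep = find_tsd(fam)
        model = fit_target_site_model(rep, fam)
        assert model.annotated == f"|{rep.motif}|"

    def test_no_consensus_tsd_gives_none(self, rng):
        elem = rand_seq(rng, 200)
        fam = [(rand_seq(rng, 40), elem, rand_seq(rng, 40)) for _ in range(10)]
        rep = find_tsd(fam)
        assert fit_target_site_model(rep, fam) is None


class TestBoundaryLogo:
    def test_invariant_position_has_two_bits(self, rng):
        fam = [(rand_seq(rng, 14) + "G", rand_seq(rng, 50), rand_seq(rng, 11))
               for _ in range(20)]
        logo5, logo3 = boundary_logo(fam)
        assert logo5.ic[-1] == pytest.approx(2.0)

    def test_frequencies_sum_to_one(self, rng):
        fam = [(rand_seq(rng, 20), rand_seq(rng, 50), rand_seq(rng, 20))
               for _ in range(10)]
        logo5, logo3 = boundary_logo(fam)
        for logo in (logo5, logo3):
            np.testing.assert_allclose(logo.freqs.sum(axis=1), 1.0)
            assert ((logo.ic >= 0) & (logo.ic <= 2)).all()

    def test_uniform_random_flanks_have_near_zero_ic(self, rng):
        fam = [(rand_seq(rng, 15), "ACGT" * 10, rand_seq(rng, 11))
               for _ in range(1000)]
        logo5, logo3 = boundary_logo(fam)
        assert abs(logo5.ic.mean()) < 0.05
        assert abs(logo3.ic.mean()) < 0.05

    def test_short_flanks_excluded_with_warning(self, rng):
        fam = [(rand_seq(rng, 15), "ACGT" * 10, rand_seq(rng, 11))
               for _ in range(5)]
        fam.append(("AC", "ACGT" * 10, "GT"))
        with pytest.warns(UserWarning):
            logo5, _ = boundary_logo(fam)
        assert logo5.n_seqs == 5
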