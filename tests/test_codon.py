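import itertools
import math

import numpy as np
import pytest

from auxiaa.codon import (
    SENSE_CODONS,
    CodonAlignment,
    align_proteins_global,
    estimate_kaks_myn,
    estimate_kaks_ng86,
    omega_ratio,
    project_to_codons,
)
from auxiaa.simulate import simulate_divergent_pair

from ng86_oracle import ng86 as oracle_ng86


def codon_aln(a_codons, b_codons):
    return CodonAlignment(tuple(zip(a_codons, b_codons)))


def split_codons(cds):
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def brute_force_global_score(a, b, matrix, gap_open=10.0, gap_extend=0.1):
    """Optimal affine-gap global score by exhaustive enumeration of all
    alignments (as monotone edit paths), for tiny strings only."""
    best = -math.inf

    def gap_cost(length):
        return gap_open + gap_extend * (length - 1) if length else 0.0

    def rec(i, j, score, last):  # last: 'm', 'd', 'i' or None
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            extra = gap_extend if last == "d" else gap_open
            rec(i + 1, j, score - extra, "d")
        if j < len(b):
            extra = gap_extend if last == "i" else gap_open
            rec(i, j + 1, score - extra, "i")

    rec(0, 0, 0.0, None)
    return best


class TestAlignment:
    def test_identical_self_alignment(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("GONNET1992")
        aln = align_proteins_global("MSTLV", "MSTLV")
        assert aln.aligned_a == aln.aligned_b == "MSTLV"
        assert aln.score == pytest.approx(sum(m[c, c] for c in "MSTLV"))

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACDEF", "ACEF"),
            ("AAAA", "WWWW"),
            ("MW", "MVW"),
            ("ACDE", "A"),
        ],
    )
    def test_optimal_score_matches_enumeration(self, a, b):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("GONNET1992")
        aln = align_proteins_global(a, b)
        assert aln.score == pytest.approx(brute_force_global_score(a, b, m))

    def test_non_residue_characters_rejected(self):
        with pytest.raises(ValueError):
            align_proteins_global("AC1E", "ACDE")


class TestCodonProjection:
    def test_two_codon_pairs(self):
        aln = align_proteins_global("MK", "MK")
        ca = project_to_codons(aln, "ATGAAA", "ATGAAG")
        assert ca.codon_pairs == (("ATG", "ATG"), ("AAA", "AAG"))

    def test_gap_column_dropped(self):
        aln = align_proteins_global("ACDEF", "ACEF")
        ca = project_to_codons(
            aln, "GCTTGTGATGAATTT", "GCTTGTGAATTT"
        )
        assert len(ca) == 4
        assert ca.dropped_columns == 1

    def test_length_mismatch_names_sequence(self):
        aln = align_proteins_global("MK", "MK")
        with pytest.raises(ValueError, match="sequence b"):
            project_to_codons(aln, "ATGAAA", "ATGAAAG")

    def test_translation_mismatch_rejected(self):
        aln = align_proteins_global("MK", "MK")
        with pytest.raises(ValueError, match="translate"):
            project_to_codons(aln, "ATGAAA", "ATGCCC")

    def test_ambiguous_codon_dropped(self):
        aln = align_proteins_global("MKK", "MKK")
        ca = project_to_codons(aln, "ATGAANAAA", "ATGAAAAAA")
        assert len(ca) == 2 and ca.dropped_columns == 1


class TestNG86:
    def test_identical_pair_zero_rates(self):
        r = estimate_kaks_ng86(codon_aln(["ATG", "AAA"], ["ATG", "AAA"]))
        assert r.ka == 0.0 and r.ks == 0.0 and r.omega is None

    def test_hand_worked_six_codon_example(self):
        a = split_codons("ATGTTTGCTGCAGCCGCG")
        b = split_codons("ATGTTCGCTGCAGCCGCG")
        r = estimate_kaks_ng86(codon_aln(a, b))
        assert r.sites.S == pytest.approx(13 / 3)
        assert r.ka == 0.0
        assert r.ks == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 13)))
        assert r.ks == pytest.approx(0.2758, abs=5e-5)

    def test_site_conservation_exact(self):
        rng = np.random.default_rng(0)
        codons = list(rng.choice(SENSE_CODONS, size=120))
        r = estimate_kaks_ng86(codon_aln(codons, codons))
        assert r.sites.S + r.sites.N == pytest.approx(3 * len(codons), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = list(rng.choice(SENSE_CODONS, size=80))
        b = list(rng.choice(SENSE_CODONS, size=80))
        fwd = estimate_kaks_ng86(codon_aln(a, b))
        rev = estimate_kaks_ng86(codon_aln(b, a))
        assert fwd.ka == pytest.approx(rev.ka, abs=1e-12)
        assert fwd.ks == pytest.approx(rev.ks, abs=1e-12)

    def test_oracle_equivalence_all_single_codon_pairs(self):
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            mine = estimate_kaks_ng86(codon_aln([ca], [cb]))
            oka, oks, (S, N) = oracle_ng86([(ca, cb)])
            assert mine.sites.S == pytest.approx(S, abs=1e-10)
            for got, want in ((mine.ka, oka), (mine.ks, oks)):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-10)

    def test_oracle_equivalence_random_long_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a, b = simulate_divergent_pair(200, 0.4, 0.5, 2.0, seed=rng)
            pairs = list(zip(split_codons(a), split_codons(b)))
            mine = estimate_kaks_ng86(CodonAlignment(tuple(pairs)))
            oka, oks, _ = oracle_ng86(pairs)
            assert mine.ka == pytest.approx(oka, abs=1e-10)
            assert mine.ks == pytest.approx(oks, abs=1e-10)

    def test_extra_synonymous_difference_never_decreases_ks(self):
        # append one synonymous difference to a baseline alignment
        base = [("GGG", "GGG")] * 30 + [("TTT", "TTC")]
        more = base + [("GCT", "GCC")]
        ks0 = estimate_kaks_ng86(CodonAlignment(tuple(base))).ks
        ks1 = estimate_kaks_ng86(CodonAlignment(tuple(more))).ks
        assert ks1 >= ks0 - 1e-12

    def test_saturation_reported_not_thrown(self):
        # every codon pair maximally synonymous-different
        pairs = [("TTT", "TTC")] * 5
        r = estimate_kaks_ng86(CodonAlignment(tuple(pairs)))
        assert r.ks is None  # ps = 1 >= 3/4


class TestMYN:
    def test_identical_pair_zero(self):
        codons = ["ATG", "AAA", "GCT", "TTT", "CGA", "GGG", "TAT", "CAA", "AAG", "GTT"]
        r = estimate_kaks_myn(codon_aln(codons, codons))
        assert r.ka == 0.0 and r.ks == 0.0

    def test_small_alignment_guard(self):
        with pytest.raises(ValueError):
            estimate_kaks_myn(codon_aln(["ATG"] * 5, ["ATG"] * 5))

    def test_agrees_with_ng86_at_low_divergence(self):
        rng = np.random.default_rng(7)
        rel = []
        for i in range(20):
            a, b = simulate_divergent_pair(500, 0.2, 0.2, 1.0, seed=rng)
            ca = CodonAlignment(tuple(zip(split_codons(a), split_codons(b))))
            ng, myn = estimate_kaks_ng86(ca), estimate_kaks_myn(ca)
            if ng.omega and myn.omega:
                rel.append(abs(myn.omega - ng.omega) / ng.omega)
        # with kappa = 1 the two methods see the same process
        assert np.median(rel) < 0.15

    def test_kappa_recovered_from_kappa4_data(self):
        rng = np.random.default_rng(11)
        kappas = []
        for _ in range(10):
            a, b = simulate_divergent_pair(500, 0.4, 0.3, 4.0, seed=rng)
            ca = CodonAlignment(tuple(zip(split_codons(a), split_codons(b))))
            kappas.append(estimate_kaks_myn(ca).kappa)
        assert 2.5 <= float(np.median(kappas)) <= 6.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = simulate_divergent_pair(200, 0.3, 0.4, 2.0, seed=rng)
        ca = CodonAlignment(tuple(zip(split_codons(a), split_codons(b))))
        cb = CodonAlignment(tuple(zip(split_codons(b), split_codons(a))))
        fwd, rev = estimate_kaks_myn(ca), estimate_kaks_myn(cb)
        assert fwd.ka == pytest.approx(rev.ka, abs=1e-12)
        assert fwd.ks == pytest.approx(rev.ks, abs=1e-12)


class TestOmegaRatio:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (4.3721, 2.6149, 1.6720),
            (0.0372, 0.0869, 0.4281),
            (0.0, 0.5, 0.0),
        ],
    )
    def test_reported_ratios(self, ka, ks, expected):
        assert omega_ratio(ka, ks) == expected

    def test_zero_ks_undefined(self):
        assert omega_ratio(0.1, 0.0) is None
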