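import itertools

import pytest

from auxiaa.duplication import (
    ParalogPair,
    assign_segmental,
    candidate_pairs,
    duplication_summary,
    find_tandem_pairs,
    pairwise_identity,
)
from auxiaa.seqio import CollinearityBlock, GeneModel


def brute_force_best_identity(a, b):
    """Identity of the best-scoring alignment by exhaustive enumeration
    of all gapped alignments of two short strings (match 1, else 0,
    maximizing identical pairs)."""
    best = 0
    la, lb = len(a), len(b)

    def rec(i, j, same):
        nonlocal best
        if i == la or j == lb:
            best = max(best, same)
            return
        rec(i + 1, j + 1, same + (a[i] == b[j]))
        rec(i + 1, j, same)
        rec(i, j + 1, same)

    rec(0, 0, 0)
    return best


PROT = "MSTLVEAWYK"


def gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, start, end, "+", ())


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity(PROT, PROT) == 100.0

    def test_direct_count(self):
        assert pairwise_identity("AAAA", "AATT") == 50.0

    def test_gapped_identity_not_above_brute_force(self):
        # the aligner maximizes Gonnet score, not raw identity, so its
        # identity can never exceed the identity-maximizing alignment
        a, b = "MSTWLVK", "MSTLVK"
        ident = pairwise_identity(a, b)
        upper = 100.0 * brute_force_best_identity(a, b) / min(len(a), len(b))
        assert ident <= upper + 1e-9
        assert ident == 100.0  # one gap resolves the insertion here

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", PROT)


class TestTandemRule:
    def test_close_similar_pair_is_tandem(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr1", 12000, 13000)]
        pairs = find_tandem_pairs(models, {"a": PROT, "b": PROT})
        assert len(pairs) == 1
        assert pairs[0].classification == "tandem"
        assert pairs[0].distance_bp == 10000

    def test_distance_bound_excludes(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr1", 62001, 63000)]
        assert find_tandem_pairs(models, {"a": PROT, "b": PROT}) == []

    def test_identity_bound_excludes(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr1", 12000, 13000)]
        # 40% identical, below the >50% homology floor
        assert pairwise_identity("ACDEFGHIKL", "ACDEQNSTYV") == 40.0
        assert find_tandem_pairs(models, {"a": "ACDEFGHIKL", "b": "ACDEQNSTYV"}) == []

    def test_cross_chromosome_never_tandem(self):
        models = [gene("a", "chr1", 1000, 2000), gene("b", "chr2", 1000, 2000)]
        assert find_tandem_pairs(models, {"a": PROT, "b": PROT}) == []

    def test_missing_protein_is_error(self):
        models = [gene("a", "chr1", 1, 10), gene("b", "chr1", 100, 110)]
        with pytest.raises(KeyError, match="b"):
            find_tandem_pairs(models, {"a": PROT})


class TestSegmentalOverlay:
    def test_anchored_distant_pair_is_segmental(self):
        pairs = [ParalogPair("a", "b", 80.0, None, "unlinked")]
        blocks = [CollinearityBlock("b1", (("a", "b"),))]
        (out,) = assign_segmental(pairs, blocks)
        assert out.classification == "segmental"

    def test_tandem_and_anchored_is_both(self):
        pairs = [ParalogPair("a", "b", 80.0, 10_000, "tandem")]
        blocks = [CollinearityBlock("b1", (("b", "a"),))]  # order-insensitive
        (out,) = assign_segmental(pairs, blocks)
        assert out.classification == "both"

    def test_unanchored_distant_pair_is_unlinked(self):
        pairs = [ParalogPair("a", "b", 80.0, None, "unlinked")]
        (out,) = assign_segmental(pairs, [])
        assert out.classification == "unlinked"

    def test_swap_invariance(self):
        blocks = [CollinearityBlock("b1", (("a", "b"),))]
        fwd = assign_segmental([ParalogPair("a", "b", 60.0, None, "unlinked")], blocks)
        rev = assign_segmental([ParalogPair("b", "a", 60.0, None, "unlinked")], blocks)
        assert fwd[0].classification == rev[0].classification == "segmental"


class TestSummary:
    def test_worked_species_percentages(self):
        # 29 genes; 22 segmentally and 6 tandemly involved
        genes = [f"g{i}" for i in range(29)]
        species_of = {g: "A. thaliana" for g in genes}
        pairs = [
            ParalogPair(genes[2 * i], genes[2 * i + 1], 80.0, None, "segmental")
            for i in range(11)
        ]
        pairs += [
            ParalogPair(genes[22 + 2 * i], genes[23 + 2 * i], 80.0, 10, "tandem")
            for i in range(3)
        ]
        (summary,) = duplication_summary(pairs, genes, species_of)
        assert (summary.seg, summary.tan, summary.total) == (22, 6, 29)
        assert summary.seg_pct == 75.86
        assert summary.tan_pct == 20.69
        assert summary.seg_and_tan == 0

    def test_no_pairs_all_zero(self):
        (summary,) = duplication_summary([], ["g1", "g2"], {"g1": "s", "g2": "s"})
        assert summary.seg_pct == summary.tan_pct == 0.0

    def test_both_pairs_count_in_each_class(self):
        genes = ["g1", "g2"]
        (summary,) = duplication_summary(
            [ParalogPair("g1", "g2", 90.0, 5, "both")],
            genes,
            {g: "s" for g in genes},
        )
        assert summary.seg == summary.tan == summary.seg_and_tan == 2

    def test_candidate_universe_covers_all_pairs(self):
        models = [
            gene("a", "chr1", 1000, 2000),
            gene("b", "chr1", 12000, 13000),
            gene("c", "chr2", 1000, 2000),
        ]
        prots = {"a": PROT, "b": PROT, "c": PROT}
        pairs = candidate_pairs(models, prots)
        assert len(pairs) == 3
        by_key = {frozenset((p.gene_a, p.gene_b)): p for p in pairs}
        assert by_key[frozenset(("a", "b"))].classification == "tandem"
        assert by_key[frozenset(("a", "c"))].distance_bp is None
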