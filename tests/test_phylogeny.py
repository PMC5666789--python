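import numpy as np
import pytest
from scipy.integrate import quad

from auxiaa.phylogeny import (
    DistanceCorrectionParams,
    DistanceMatrix,
    SisterPair,
    TreeNode,
    bootstrap_support,
    correct_distance,
    extract_sister_pairs,
    nj_tree,
    p_distance_matrix,
    to_newick,
)


def random_binary_tree(rng, n_leaves):
    """Random topology with branch lengths in [0.1, 2.0]."""
    nodes = [TreeNode(label=f"t{i}", branch_length=float(rng.uniform(0.1, 2.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = TreeNode(
            children=[nodes[i], nodes[j]],
            branch_length=float(rng.uniform(0.1, 2.0)),
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes)


def tree_distances(tree):
    """Leaf-to-leaf path-length matrix of a tree (the additive metric)."""
    dists = {}

    def below(node, acc):
        if node.is_leaf:
            return {node.label: acc}
        out = {}
        for c in node.children:
            out.update(below(c, acc + c.branch_length))
        return out

    def collect(node):
        groups = [below(c, c.branch_length) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        dists[frozenset((la, lb))] = da + db
        for c in node.children:
            if not c.is_leaf:
                collect(c)

    collect(tree)
    taxa = sorted(l.label for l in tree.leaves())
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dists[frozenset((taxa[i], taxa[j]))]
    return DistanceMatrix(tuple(taxa), d)


class TestPDistance:
    def test_direct_proportion(self):
        dm = p_distance_matrix({"a": "AAAA", "b": "AATT"})
        assert dm.d[0, 1] == 0.5

    def test_identical_rows_zero(self):
        dm = p_distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert dm.d[0, 1] == 0.0

    def test_pairwise_deletion(self):
        dm = p_distance_matrix({"a": "AA-A", "b": "AACA"})
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValueError, match="a"):
            p_distance_matrix({"a": "A--", "b": "-AA"})

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACDE"), size=30)) for i in range(5)
        }
        dm = p_distance_matrix(seqs)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)


class TestGammaInvariantCorrection:
    def test_zero_distance_maps_to_zero(self):
        dm = DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        out = correct_distance(dm, DistanceCorrectionParams(alpha=0.5, p_inv=0.3))
        assert out.d[0, 1] == 0.0

    def test_large_alpha_limit_is_log_correction(self):
        # alpha -> inf recovers the no-rate-variation multiple-hit
        # correction -ln(1 - d), the transform's true limit
        d = np.array([[0, 0.3], [0.3, 0]])
        dm = DistanceMatrix(("a", "b"), d)
        out = correct_distance(dm, DistanceCorrectionParams(alpha=1e6, p_inv=0.0))
        assert out.d[0, 1] == pytest.approx(-np.log(0.7), abs=1e-6)

    def test_small_distances_nearly_unchanged(self):
        d = np.array([[0, 1e-3], [1e-3, 0]])
        dm = DistanceMatrix(("a", "b"), d)
        out = correct_distance(dm, DistanceCorrectionParams(alpha=2.0, p_inv=0.0))
        assert out.d[0, 1] == pytest.approx(1e-3, rel=1e-2)

    def test_against_numerically_integrated_transform(self):
        # the alpha=1, p_inv=0 correction equals the expectation of the
        # per-site transform under the gamma(1,1) rate mixture:
        # d' = \int_0^inf e^{-r} * (-(expm1 inverse)) ... evaluated via the
        # closed form's defining integral d' = \int_0^d (1 - x)^{-(1+1/a)/1} dx
        a = 1.0
        d = 0.3
        integral, _ = quad(lambda x: (1.0 - x) ** (-(1.0 + 1.0 / a)), 0.0, d)
        dm = DistanceMatrix(("x", "y"), np.array([[0, d], [d, 0]]))
        out = correct_distance(dm, DistanceCorrectionParams(alpha=a))
        assert out.d[0, 1] == pytest.approx(integral, rel=1e-8)

    def test_correction_never_decreases(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.6, size=6)
        d = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        d[iu] = vals
        d = d + d.T
        dm = DistanceMatrix(tuple("abcd"), d)
        out = correct_distance(dm, DistanceCorrectionParams(alpha=0.7, p_inv=0.1))
        assert (out.d >= dm.d - 1e-12).all()

    def test_saturated_entry_is_error(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.95], [0.95, 0]]))
        with pytest.raises(ValueError):
            correct_distance(dm, DistanceCorrectionParams(alpha=1.0, p_inv=0.1))


class TestNeighborJoining:
    def test_four_point_worked_example(self):
        taxa = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(taxa, d))
        rec = tree_distances(tree)
        assert rec.taxa == taxa
        assert np.allclose(rec.d, d)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        assert np.allclose(tree_distances(tree).d, d)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0.0]])))

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(tuple("abcd"), d)
        t1, t2 = to_newick(nj_tree(dm)), to_newick(nj_tree(dm))
        assert t1 == t2

    def test_exact_recovery_random_additive_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(5, 13))
            truth = random_binary_tree(rng, n)
            dm = tree_distances(truth)
            rebuilt = tree_distances(nj_tree(dm))
            assert rebuilt.taxa == dm.taxa
            # recovering the full additive metric pins down both the
            # topology and every branch length
            assert np.allclose(rebuilt.d, dm.d, atol=1e-9)


class TestBootstrap:
    MSA = {
        "a1": "AAAAAAAAAACCCCCTTTTT",
        "a2": "AAAAAAAAAACCCCCTTTTG",
        "b1": "TTTTTTTTTTGGGGGAAAAA",
        "b2": "TTTTTTTTTTGGGGGAAAAC",
        "c1": "CCCCCGGGGGAAAAAGGGGG",
    }

    def test_separated_clades_get_full_support(self):
        tree = bootstrap_support(self.MSA, replicates=200, seed=5)
        supports = [
            n.support for n in tree.walk() if n.support is not None
        ]
        assert supports and all(s >= 99 for s in supports)

    def test_single_replicate_supports_are_0_or_100(self):
        tree = bootstrap_support(self.MSA, replicates=1, seed=9)
        for n in tree.walk():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_same_seed_identical_supports(self):
        t1 = bootstrap_support(self.MSA, replicates=50, seed=3)
        t2 = bootstrap_support(self.MSA, replicates=50, seed=3)
        assert to_newick(t1) == to_newick(t2)


class TestSisterPairs:
    def cherry_tree(self, support):
        cherry = TreeNode(
            children=[TreeNode(label="x"), TreeNode(label="y")], support=support
        )
        return TreeNode(children=[cherry, TreeNode(label="z"), TreeNode(label="w")])

    def test_above_threshold_reported(self):
        assert extract_sister_pairs(self.cherry_tree(95)) == [
            SisterPair("x", "y", 95)
        ]

    def test_boundary_is_strict(self):
        assert extract_sister_pairs(self.cherry_tree(90)) == []

    def test_no_qualifying_cherries_empty(self):
        inner = TreeNode(
            children=[TreeNode(label="a"), TreeNode(label="b")], support=80
        )
        mid = TreeNode(children=[inner, TreeNode(label="c")], support=99)
        root = TreeNode(children=[mid, TreeNode(label="d"), TreeNode(label="e")])
        assert extract_sister_pairs(root) == []

    def test_only_cherries_reported_in_caterpillar(self):
        inner = TreeNode(
            children=[TreeNode(label="a"), TreeNode(label="b")], support=99
        )
        mid = TreeNode(children=[inner, TreeNode(label="c")], support=99)
        root = TreeNode(children=[mid, TreeNode(label="d"), TreeNode(label="e")])
        assert extract_sister_pairs(root) == [SisterPair("a", "b", 99)]


class TestNewick:
    def test_supports_written_as_internal_labels(self):
        cherry = TreeNode(
            children=[
                TreeNode(label="x", branch_length=1.0),
                TreeNode(label="y", branch_length=2.0),
            ],
            support=97.0,
            branch_length=0.5,
        )
        root = TreeNode(children=[cherry, TreeNode(label="z", branch_length=3.0)])
        assert to_newick(root) == "((x:1,y:2)97:0.5,z:3);"

    def test_punctuated_labels_quoted(self):
        root = TreeNode(
            children=[
                TreeNode(label="sp one", branch_length=1.0),
                TreeNode(label="b", branch_length=1.0),
            ]
        )
        assert to_newick(root).startswith("('sp one':1,")
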