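"""p-distance matrices, neighbor-joining trees, bootstrap and cherries.

Distances are raw p-distances under pairwise deletion, optionally
corrected with a gamma + invariant-sites transform.  Trees are built
with the Saitou–Nei neighbor-joining algorithm (deterministic
tie-breaks, negative branch lengths clamped to zero) and bootstrap
supports come from column resampling.  Sister pairs — cherries with
support above a threshold (strictly greater, matching the ">90%"
reporting convention) — can be extracted from a supported tree.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "DistanceMatrix",
    "DistanceCorrectionParams",
    "TreeNode",
    "SisterPair",
    "p_distance_matrix",
    "correct_distance",
    "nj_tree",
    "bootstrap_support",
    "extract_sister_pairs",
    "to_newick",
]

GAP = "-"


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class DistanceCorrectionParams:
    """Gamma shape ``alpha`` and invariant-site proportion ``p_inv``."""

    alpha: float
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")


@dataclass
class TreeNode:
    """Node of an (unrooted, trifurcating-root) phylogeny."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class SisterPair:
    taxon_a: str
    taxon_b: str
    support: float


def _as_seq_mapping(
    msa: Mapping[str, str] | Sequence[SequenceRecord],
) -> dict[str, str]:
    if isinstance(msa, Mapping):
        seqs = dict(msa)
    else:
        seqs = {r.id: r.residues for r in msa}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    return seqs


def p_distance_matrix(
    msa: Mapping[str, str] | Sequence[SequenceRecord],
    columns: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise p-distances under pairwise deletion.

    ``columns`` optionally restricts/reorders alignment columns (used by
    the bootstrap).  A pair with no gap-free shared column is an error.
    """
    seqs = _as_seq_mapping(msa)
    taxa = tuple(seqs)
    arr = np.array([list(seqs[t]) for t in taxa])
    if columns is not None:
        arr = arr[:, columns]
    nongap = arr != GAP
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            diffs = int((arr[i, comparable] != arr[j, comparable]).sum())
            d[i, j] = d[j, i] = diffs / m
    return DistanceMatrix(taxa, d)


def correct_distance(
    dm: DistanceMatrix, params: DistanceCorrectionParams
) -> DistanceMatrix:
    """Gamma + invariant-sites correction, element-wise.

    d' = alpha * (1 - p_inv) * ((1 - d/(1 - p_inv))^(-1/alpha) - 1).
    The transform is increasing, d' >= d, and reduces to the identity in
    the limit alpha -> inf, p_inv -> 0.  An entry with d >= 1 - p_inv is
    undefined and raises.
    """
    a, pinv = params.alpha, params.p_inv
    d = dm.d
    if (d >= 1.0 - pinv).any():
        bad = np.argwhere(d >= 1.0 - pinv)[0]
        raise ValueError(
            f"distance {d[bad[0], bad[1]]:.4f} between "
            f"{dm.taxa[bad[0]]!r} and {dm.taxa[bad[1]]!r} is >= 1 - p_inv"
        )
    corrected = a * (1.0 - pinv) * ((1.0 - d / (1.0 - pinv)) ** (-1.0 / a) - 1.0)
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(dm.taxa, corrected)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Agglomeration follows the Q criterion; ties go to the
    lexicographically smallest pair of current node indices.  Negative
    branch-length estimates are clamped to zero.  The result is rooted
    at a trifurcation (the last three nodes).  Exact on additive
    matrices.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest (i, j) index pair on ties
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < best[0] - 1e-12:
                    best = (q[i, j], i, j)
        _, i, j = best
        fi, fj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[fi], nodes[fj]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining actives
        new_row = np.zeros(d.shape[0] + 1)
        for k_pos, fk in enumerate(active):
            if fk in (fi, fj):
                continue
            new_row[fk] = 0.5 * (d[fi, fk] + d[fj, fk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [x for x in active if x not in (fi, fj)] + [len(nodes) - 1]

    fi, fj, fk = active
    dij, dik, djk = d[fi, fj], d[fi, fk], d[fj, fk]
    root = TreeNode(children=[nodes[fi], nodes[fj], nodes[fk]])
    nodes[fi].branch_length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[fj].branch_length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[fk].branch_length = max(0.5 * (dik + djk - dij), 0.0)
    return root


def _canonical_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Splits canonicalized to the side not containing the reference taxon."""
    all_leaves = tree.leaf_labels()
    ref = min(all_leaves)
    out = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_labels()
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        out.add(side if ref not in side else all_leaves - side)
    return out


def bootstrap_support(
    msa: Mapping[str, str] | Sequence[SequenceRecord],
    replicates: int = 1000,
    seed: int = 0,
    correction: DistanceCorrectionParams | None = None,
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree and the support of each reference bipartition is the
    percentage of replicate trees containing it.  Deterministic given
    ``seed``.  Replicates in which a taxon pair loses all comparable
    columns are skipped (supports stay percentages of usable replicates).
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    seqs = _as_seq_mapping(msa)
    L = len(next(iter(seqs.values())))

    def build(columns: np.ndarray | None) -> TreeNode:
        dm = p_distance_matrix(seqs, columns)
        if correction is not None:
            dm = correct_distance(dm, correction)
        return nj_tree(dm)

    reference = build(None)
    ref_splits = _canonical_splits(reference)
    counts: dict[frozenset[str], int] = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            rep = build(cols)
        except ValueError:
            continue
        used += 1
        rep_splits = _canonical_splits(rep)
        for s in ref_splits & rep_splits:
            counts[s] += 1

    all_leaves = reference.leaf_labels()
    ref = min(all_leaves)
    for node in reference.walk():
        if node is reference or node.is_leaf:
            continue
        side = node.leaf_labels()
        if len(side) < 2 or len(side) > len(all_leaves) - 2:
            continue
        canon = side if ref not in side else all_leaves - side
        node.support = 100.0 * counts[canon] / used if used else 0.0
    return reference


def extract_sister_pairs(tree: TreeNode, min_support: float = 90.0) -> list[SisterPair]:
    """Cherries with bootstrap support strictly above ``min_support``.

    Each leaf can belong to at most one cherry by construction.
    """
    pairs: list[SisterPair] = []
    for node in tree.walk():
        if node.is_leaf or len(node.children) != 2:
            continue
        a, b = node.children
        if a.is_leaf and b.is_leaf and node.support is not None:
            if node.support > min_support:
                ta, tb = sorted((a.label, b.label))
                pairs.append(SisterPair(ta, tb, node.support))
    return sorted(pairs, key=lambda p: (p.taxon_a, p.taxon_b))


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def to_newick(tree: TreeNode, with_supports: bool = True) -> str:
    """Newick string; supports are written as internal-node labels."""

    def render(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            return f"{_quote(node.label)}:{node.branch_length:.6g}"
        inner = ",".join(render(c, False) for c in node.children)
        label = ""
        if with_supports and node.support is not None:
            label = f"{node.support:.6g}"
        if is_root:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.branch_length:.6g}"

    return render(tree, True) + ";"
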