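"""Protein-guided codon alignment and Ka/Ks estimation.

Paralog pairs are aligned at the protein level (global affine
alignment, Gonnet-250 scoring, opening 10 / extension 0.1), projected
back onto their coding sequences codon-by-codon, and the synonymous
(Ks) and nonsynonymous (Ka) substitution rates are estimated with two
approximate counting methods:

* NG86 — Nei–Gojobori fractional site counting, equal weighting of all
  shortest substitution pathways through multi-difference codons, and a
  Jukes–Cantor multiple-hit correction.
* MYN — a modified Yang–Nielsen estimator: the transition/transversion
  ratio kappa is estimated from four-fold degenerate and nondegenerate
  sites with a Kimura-type correction, sites are counted with kappa and
  codon-usage weighting, and transitional/transversional differences at
  synonymous and nonsynonymous sites are corrected separately
  (HKY-flavoured) to give Ka and Ks.

ω = Ka/Ks summarizes selection: below one purifying, above one positive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
    "PairwiseProteinAlignment",
    "CodonAlignment",
    "SiteCounts",
    "KaKsResult",
    "align_proteins_global",
    "project_to_codons",
    "estimate_kaks_ng86",
    "estimate_kaks_myn",
    "omega_ratio",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_NUCS = "ACGT"
_TRANSITions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon; '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def is_transition(n1: str, n2: str) -> bool:
    return (n1, n2) in _TRANSITions


@dataclass(frozen=True)
class PairwiseProteinAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("alignment contains a double-gap column")

    def identity_percent(self) -> float:
        """Identical columns over gap-free columns, as a percentage."""
        same = comparable = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" or cb == "-":
                continue
            comparable += 1
            if ca == cb:
                same += 1
        if comparable == 0:
            return 0.0
        return 100.0 * same / comparable


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free, stop-free, unambiguous aligned codon pairs."""

    codon_pairs: tuple[tuple[str, str], ...]
    dropped_columns: int = 0

    def __post_init__(self) -> None:
        for ca, cb in self.codon_pairs:
            if ca not in _TABLE.forward_table or cb not in _TABLE.forward_table:
                raise ValueError(f"non-sense codon pair ({ca}, {cb})")

    def __len__(self) -> int:
        return len(self.codon_pairs)


@dataclass(frozen=True)
class SiteCounts:
    S: float
    N: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.N < 0:
            raise ValueError("site counts must be nonnegative")


@dataclass(frozen=True)
class KaKsResult:
    pair: str
    ka: float | None
    ks: float | None
    omega: float | None
    method: Literal["NG86", "MYN"]
    kappa: float | None = None
    sites: SiteCounts | None = None


_GONNET = None


def _gonnet_matrix():
    global _GONNET
    if _GONNET is None:
        _GONNET = substitution_matrices.load("GONNET1992")
    return _GONNET


def align_proteins_global(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.1,
) -> PairwiseProteinAlignment:
    """Optimal global affine-gap protein alignment (Gonnet 250 default).

    Gap penalties follow the ClustalX convention (opening 10,
    extension 0.1).  Deterministic: the aligner's first co-optimal
    traceback is returned.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if matrix is None:
        matrix = _gonnet_matrix()
    alphabet = set(str(matrix.alphabet))
    for name, seq in (("first", a), ("second", b)):
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"{name} sequence has non-residue characters {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return PairwiseProteinAlignment(sa, sb, float(aln.score))


def project_to_codons(
    alignment: PairwiseProteinAlignment, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Back-translate a protein alignment to aligned codon pairs.

    Each CDS must be exactly three times its ungapped protein length and
    translate to it.  Columns containing a gap, a stop codon or a codon
    with ambiguous bases are dropped (counted in ``dropped_columns``).
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    pairs: list[tuple[str, str]] = []
    dropped = 0
    ia = ib = 0
    for name, aligned, cds in (
        ("a", alignment.aligned_a, cds_a),
        ("b", alignment.aligned_b, cds_b),
    ):
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"sequence {name}: CDS length {len(cds)} != 3 x protein length "
                f"{len(protein)}"
            )
        translated = str(Seq(cds).translate())
        for p, t in zip(protein, translated):
            if p != t and p != "X" and t != "X":
                raise ValueError(f"sequence {name}: CDS does not translate to protein")
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ca != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            dropped += 1
            continue
        if codon_a not in _TABLE.forward_table or codon_b not in _TABLE.forward_table:
            dropped += 1
            continue
        pairs.append((codon_a, codon_b))
    return CodonAlignment(tuple(pairs), dropped)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _ng86_codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one sense codon.

    At each position the three alternative nucleotides are examined;
    changes producing stop codons do not count as synonymous, and the
    denominator stays 3 per position so S + N = 3 exactly.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def _pathway_steps(codon_a: str, codon_b: str):
    """All shortest substitution pathways between two codons.

    Yields, for each ordering of the differing positions, the list of
    (from_codon, to_codon) single-nucleotide steps; pathways passing
    through stop codons are skipped by the caller.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in itertools.permutations(diff):
        steps = []
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            current = nxt
        yield steps


@lru_cache(maxsize=None)
def _ng86_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair under equal pathway weighting.

    Pathways through stop codons are excluded and the weights
    renormalized; if every pathway is blocked, all are used.
    """
    if codon_a == codon_b:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for steps in _pathway_steps(codon_a, codon_b):
        sd = nd = 0.0
        through_stop = False
        for frm, to in steps:
            if to in STOP_CODONS:
                through_stop = True
            if translate_codon(frm) == translate_codon(to):
                sd += 1
            else:
                nd += 1
        (blocked if through_stop else valid).append((sd, nd))
    use = valid if valid else blocked
    sd = sum(x[0] for x in use) / len(use)
    nd = sum(x[1] for x in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def estimate_kaks_ng86(
    codon_alignment: CodonAlignment, pair: str = "<pair>"
) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction.

    Sites are counted per codon and averaged over the two sequences;
    differences use equal weighting of all shortest pathways.  A
    saturated proportion (>= 3/4) leaves the corresponding rate
    undefined; ω is undefined unless Ks > 0.
    """
    if len(codon_alignment) < 1:
        raise ValueError("need at least one codon pair")
    S = N = Sd = Nd = 0.0
    for ca, cb in codon_alignment.codon_pairs:
        sa, na = _ng86_codon_sites(ca)
        sb, nb = _ng86_codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _ng86_pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(pair, ka, ks, omega, "NG86", sites=SiteCounts(S, N))


# ---------------------------------------------------------------------------
# MYN (modified Yang-Nielsen approximate method)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _position_degeneracy(codon: str, pos: int) -> int:
    """Number of synonymous alternatives (0..3) at one codon position."""
    aa = translate_codon(codon)
    n_syn = 0
    for nuc in _NUCS:
        if nuc == codon[pos]:
            continue
        alt = codon[:pos] + nuc + codon[pos + 1 :]
        if alt not in STOP_CODONS and translate_codon(alt) == aa:
            n_syn += 1
    return n_syn


def _kimura_two_parameter(P: float, Q: float) -> tuple[float, float, float] | None:
    """K80 distance decomposition.

    Returns (d, A, B): total distance, transitional and transversional
    components; None when the correction is undefined (saturation).
    """
    x = 1.0 - 2.0 * P - Q
    y = 1.0 - 2.0 * Q
    if x <= 0 or y <= 0:
        return None
    A = 0.5 * math.log(1.0 / x) - 0.25 * math.log(1.0 / y)
    B = 0.5 * math.log(1.0 / y)
    return A + B, A, B


def _estimate_kappa(codon_alignment: CodonAlignment) -> float:
    """kappa (ts/tv rate ratio) from four-fold and nondegenerate sites.

    Sites whose degeneracy class agrees in both codons are pooled;
    each class gives a K80-corrected kappa = 2A/B and the two are
    combined weighted by site counts.  Falls back to 1.0 when the
    correction is undefined or no transversions are seen.
    """
    counts = {4: [0, 0, 0], 0: [0, 0, 0]}  # class -> [n, ts, tv]
    for ca, cb in codon_alignment.codon_pairs:
        for pos in range(3):
            da, db = _position_degeneracy(ca, pos), _position_degeneracy(cb, pos)
            cls = None
            if da == 3 and db == 3:
                cls = 4
            elif da == 0 and db == 0:
                cls = 0
            if cls is None:
                continue
            counts[cls][0] += 1
            if ca[pos] != cb[pos]:
                if is_transition(ca[pos], cb[pos]):
                    counts[cls][1] += 1
                else:
                    counts[cls][2] += 1
    kappas: list[tuple[float, int]] = []
    for cls, (n, ts, tv) in counts.items():
        if n == 0:
            continue
        k2p = _kimura_two_parameter(ts / n, tv / n)
        if k2p is None:
            continue
        _, A, B = k2p
        if B > 1e-12 and A > 0:
            kappas.append((2.0 * A / B, n))
    if not kappas:
        return 1.0
    total = sum(n for _, n in kappas)
    return sum(k * n for k, n in kappas) / total


def _codon_frequencies(codon_alignment: CodonAlignment) -> dict[str, float]:
    counts = {c: 1.0 for c in SENSE_CODONS}  # add-one smoothing
    for ca, cb in codon_alignment.codon_pairs:
        counts[ca] += 1
        counts[cb] += 1
    total = sum(counts.values())
    return {c: v / total for c, v in counts.items()}


def _myn_codon_sites(
    codon: str, kappa: float, pi: dict[str, float]
) -> tuple[float, float]:
    """Kappa- and codon-usage-weighted (S, N) for one codon."""
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        w_syn = w_all = 0.0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            w = (kappa if is_transition(codon[pos], nuc) else 1.0) * pi[alt]
            w_all += w
            if translate_codon(alt) == aa:
                w_syn += w
        if w_all > 0:
            syn += w_syn / w_all
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _myn_pair_differences(
    codon_a: str, codon_b: str
) -> tuple[float, float, float, float]:
    """(syn-ts, syn-tv, nonsyn-ts, nonsyn-tv) differences for one pair.

    Equal weighting over stop-free shortest pathways, as in the NG86
    counting, but with every step classified by transition vs
    transversion as well as by synonymy.
    """
    if codon_a == codon_b:
        return 0.0, 0.0, 0.0, 0.0
    valid: list[tuple[float, float, float, float]] = []
    blocked: list[tuple[float, float, float, float]] = []
    for steps in _pathway_steps(codon_a, codon_b):
        sts = stv = nts = ntv = 0.0
        through_stop = False
        for frm, to in steps:
            if to in STOP_CODONS:
                through_stop = True
            pos = next(i for i in range(3) if frm[i] != to[i])
            ts = is_transition(frm[pos], to[pos])
            if translate_codon(frm) == translate_codon(to):
                sts, stv = sts + ts, stv + (not ts)
            else:
                nts, ntv = nts + ts, ntv + (not ts)
        rec = (sts, stv, nts, ntv)
        (blocked if through_stop else valid).append(rec)
    use = valid if valid else blocked
    n = len(use)
    return tuple(sum(r[i] for r in use) / n for i in range(4))  # type: ignore[return-value]


def estimate_kaks_myn(
    codon_alignment: CodonAlignment,
    pair: str = "<pair>",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> KaKsResult:
    """Modified Yang–Nielsen approximate Ka/Ks.

    kappa comes from four-fold degenerate and nondegenerate sites under
    a Kimura-type correction; sites are counted weighting transitions by
    kappa and targets by observed codon usage; transitional and
    transversional difference proportions at synonymous and
    nonsynonymous sites are corrected separately.  The site/rate pair is
    iterated to a fixed point (tolerance ``tol`` on Ka and Ks).
    """
    if len(codon_alignment) < 10:
        raise ValueError("MYN needs at least 10 codon pairs")
    pi = _codon_frequencies(codon_alignment)
    if all(ca == cb for ca, cb in codon_alignment.codon_pairs):
        S = N = 0.0
        for ca, _ in codon_alignment.codon_pairs:
            s, n = _myn_codon_sites(ca, 1.0, pi)
            S, N = S + s, N + n
        return KaKsResult(pair, 0.0, 0.0, None, "MYN", kappa=1.0,
                          sites=SiteCounts(S, N))
    kappa = _estimate_kappa(codon_alignment)

    sts = stv = nts = ntv = 0.0
    for ca, cb in codon_alignment.codon_pairs:
        d = _myn_pair_differences(ca, cb)
        sts, stv, nts, ntv = sts + d[0], stv + d[1], nts + d[2], ntv + d[3]

    ka = ks = None
    prev = (math.inf, math.inf)
    for _ in range(max_iter):
        S = N = 0.0
        for ca, cb in codon_alignment.codon_pairs:
            sa, na = _myn_codon_sites(ca, kappa, pi)
            sb, nb = _myn_codon_sites(cb, kappa, pi)
            S += (sa + sb) / 2.0
            N += (na + nb) / 2.0
        ks_k2p = _kimura_two_parameter(sts / S, stv / S) if S > 0 else None
        ka_k2p = _kimura_two_parameter(nts / N, ntv / N) if N > 0 else None
        ks = ks_k2p[0] if ks_k2p is not None else None
        ka = ka_k2p[0] if ka_k2p is not None else None
        if ka is None or ks is None:
            break  # saturated: reported as undefined, not an error
        cur = (
            ka if ka is not None else math.nan,
            ks if ks is not None else math.nan,
        )
        if (
            prev[0] == prev[0]
            and cur[0] == cur[0]
            and abs(cur[0] - prev[0]) < tol
            and abs(cur[1] - prev[1]) < tol
        ):
            break
        # kappa itself is NOT refit from the synonymous-site ts/tv split:
        # synonymous changes are structurally transition-enriched (2-fold
        # sites), so that split wildly overestimates the mutational
        # transition bias.  The degenerate-site estimate stays fixed and
        # the site counts settle in one pass.
        prev = cur
    else:
        raise RuntimeError(
            f"MYN did not converge after {max_iter} iterations "
            f"(last Ka={ka}, Ks={ks})"
        )
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(pair, ka, ks, omega, "MYN", kappa=kappa,
                      sites=SiteCounts(S, N))


def omega_ratio(ka: float, ks: float) -> float | None:
    """Ka ÷ Ks, rounded to 4 decimals for reporting; None when Ks = 0."""
    if ks == 0:
        return None
    return round(ka / ks, 4)
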