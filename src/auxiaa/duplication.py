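"""Tandem / segmental duplication-mode calling for paralog pairs.

Tandem pairs are paralogs on the same chromosome within 50 kb
(nearest gene boundaries) whose proteins are more than 50% identical
under global alignment.  Segmental pairs are those anchored in a
collinearity block.  A pair meeting both rules is classified "both";
anything else is "unlinked".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .codon import align_proteins_global
from .seqio import CollinearityBlock, GeneModel, SequenceRecord

__all__ = [
    "ParalogPair",
    "DuplicationSummary",
    "pairwise_identity",
    "find_tandem_pairs",
    "assign_segmental",
    "duplication_summary",
]

Classification = Literal["tandem", "segmental", "both", "unlinked"]

TANDEM_MAX_DISTANCE_BP = 50_000
TANDEM_IDENTITY_MIN = 50.0


@dataclass(frozen=True)
class ParalogPair:
    """One unordered paralogous gene pair with its duplication call."""

    gene_a: str
    gene_b: str
    identity_pct: float
    distance_bp: int | None
    classification: Classification

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a paralog pair cannot be a self-pair")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if self.distance_bp is not None and self.distance_bp < 0:
            raise ValueError("distance_bp must be nonnegative")

    def key(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class DuplicationSummary:
    species: str
    seg: int
    tan: int
    seg_and_tan: int
    total: int
    seg_pct: float
    tan_pct: float

    def __post_init__(self) -> None:
        if self.seg_and_tan > min(self.seg, self.tan):
            raise ValueError("Seg&Tan cannot exceed min(Seg, Tan)")


def pairwise_identity(protein_a: str, protein_b: str) -> float:
    """Global-alignment identity between two proteins, in percent.

    Identical columns over aligned gap-free columns x 100.
    """
    if not protein_a or not protein_b:
        raise ValueError("cannot compute identity of an empty sequence")
    return align_proteins_global(protein_a, protein_b).identity_percent()


def _boundary_distance(a: GeneModel, b: GeneModel) -> int:
    """Nearest-boundary distance in bp; 0 when the genes overlap."""
    if a.end < b.start:
        return b.start - a.end
    if b.end < a.start:
        return a.start - b.end
    return 0


def find_tandem_pairs(
    gene_models: Sequence[GeneModel],
    proteins: Mapping[str, str] | Sequence[SequenceRecord],
    identity_min: float = TANDEM_IDENTITY_MIN,
    max_distance: int = TANDEM_MAX_DISTANCE_BP,
) -> list[ParalogPair]:
    """Tandem duplicated pairs by the 50-kb / >50%-identity rule.

    A pair qualifies iff both genes sit on the same chromosome, their
    nearest boundaries are at most ``max_distance`` apart, and their
    protein identity strictly exceeds ``identity_min``.  Output is
    deduplicated and symmetric in gene order.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p.residues for p in proteins}
    for gm in gene_models:
        if gm.gene_id not in proteins:
            raise KeyError(f"gene {gm.gene_id!r} has no protein sequence")
    pairs: list[ParalogPair] = []
    ordered = sorted(gene_models, key=lambda g: (g.chromosome, g.start, g.gene_id))
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1 :]:
            if gb.chromosome != ga.chromosome:
                break
            dist = _boundary_distance(ga, gb)
            if dist > max_distance:
                continue
            ident = pairwise_identity(proteins[ga.gene_id], proteins[gb.gene_id])
            if ident > identity_min:
                pairs.append(
                    ParalogPair(ga.gene_id, gb.gene_id, ident, dist, "tandem")
                )
    return pairs


def candidate_pairs(
    gene_models: Sequence[GeneModel],
    proteins: Mapping[str, str] | Sequence[SequenceRecord],
    identity_min: float = TANDEM_IDENTITY_MIN,
    max_distance: int = TANDEM_MAX_DISTANCE_BP,
) -> list[ParalogPair]:
    """All unordered gene pairs with identity, distance and tandem calls.

    Family sizes are small, so every pair is scored; pairs meeting the
    tandem rule come back classified "tandem", the rest "unlinked"
    (pending collinearity overlay by :func:`assign_segmental`).
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p.residues for p in proteins}
    for gm in gene_models:
        if gm.gene_id not in proteins:
            raise KeyError(f"gene {gm.gene_id!r} has no protein sequence")
    pairs: list[ParalogPair] = []
    models = sorted(gene_models, key=lambda g: g.gene_id)
    for i, ga in enumerate(models):
        for gb in models[i + 1 :]:
            dist = (
                _boundary_distance(ga, gb)
                if ga.chromosome == gb.chromosome
                else None
            )
            ident = pairwise_identity(proteins[ga.gene_id], proteins[gb.gene_id])
            tandem = (
                dist is not None and dist <= max_distance and ident > identity_min
            )
            pairs.append(
                ParalogPair(
                    ga.gene_id,
                    gb.gene_id,
                    ident,
                    dist,
                    "tandem" if tandem else "unlinked",
                )
            )
    return pairs


def assign_segmental(
    pairs_universe: Iterable[ParalogPair],
    blocks: Sequence[CollinearityBlock],
) -> list[ParalogPair]:
    """Overlay collinearity-block evidence on a set of candidate pairs.

    A pair anchored in any block becomes "segmental"; a pair that is
    already tandem and anchored becomes "both"; a pair that is neither
    becomes "unlinked".
    """
    anchored: set[frozenset[str]] = set()
    for block in blocks:
        for a, b in block.anchor_pairs:
            anchored.add(frozenset((a, b)))
    out: list[ParalogPair] = []
    for pair in pairs_universe:
        in_block = pair.key() in anchored
        if pair.classification in ("tandem", "both"):
            cls: Classification = "both" if in_block else "tandem"
        else:
            cls = "segmental" if in_block else "unlinked"
        out.append(replace(pair, classification=cls))
    return out


def duplication_summary(
    classified_pairs: Iterable[ParalogPair],
    gene_universe: Iterable[str],
    species_of: Mapping[str, str],
) -> list[DuplicationSummary]:
    """Per-species counts of genes touched by each duplication mode.

    A gene counts toward Seg (or Tan) if it participates in at least
    one segmental/both (tandem/both) pair; percentages are of the
    species' total gene count, to two decimals.
    """
    genes = list(gene_universe)
    seg_genes: set[str] = set()
    tan_genes: set[str] = set()
    for pair in classified_pairs:
        if pair.classification in ("segmental", "both"):
            seg_genes.update((pair.gene_a, pair.gene_b))
        if pair.classification in ("tandem", "both"):
            tan_genes.update((pair.gene_a, pair.gene_b))
    by_species: dict[str, list[str]] = {}
    for g in genes:
        if g not in species_of:
            raise KeyError(f"gene {g!r} has no species mapping")
        by_species.setdefault(species_of[g], []).append(g)
    out = []
    for sp, sp_genes in by_species.items():
        total = len(sp_genes)
        seg = sum(1 for g in sp_genes if g in seg_genes)
        tan = sum(1 for g in sp_genes if g in tan_genes)
        both = sum(1 for g in sp_genes if g in seg_genes and g in tan_genes)
        out.append(
            DuplicationSummary(
                species=sp,
                seg=seg,
                tan=tan,
                seg_and_tan=both,
                total=total,
                seg_pct=round(100.0 * seg / total, 2) if total else 0.0,
                tan_pct=round(100.0 * tan / total, 2) if total else 0.0,
            )
        )
    return out


def pairs_table(pairs: Iterable[ParalogPair]) -> pd.DataFrame:
    """Classified pairs as a report table."""
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "identity_pct": round(p.identity_pct, 2),
                "distance_bp": p.distance_bp,
                "classification": p.classification,
            }
            for p in pairs
        ]
    )
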