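"""Readers and writers for the formats the pipeline touches.

Sequences travel as :class:`SequenceRecord` (protein or spliced CDS),
gene coordinates as :class:`GeneModel` parsed from GFF3 (1-based,
inclusive, ``ID``/``Parent`` attributes mandatory), and segmental
duplication evidence as :class:`CollinearityBlock` lists read from a
three-column tab-separated anchor-pair file.  The module also packages
transcriptions of the published summary tables for the 17-proteome
survey (gene counts, selected Ka/Ks pairs, and per-species NLS counts),
exposed through :func:`load_fixture_tables`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "CollinearityBlock",
    "FixtureTables",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_collinearity_blocks",
    "load_fixture_tables",
    "load_consensus_patterns",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# IUPAC nucleotide codes are tolerated on read; codons containing
# anything outside ACGT are unusable downstream.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


class FormatError(ValueError):
    """Malformed input file (names the offending record or line)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or CDS sequence."""

    id: str
    molecule: Literal["protein", "cds"]
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """Genomic placement of one gene and the ids of its spliced CDS."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: Literal["+", "-"]
    cds_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.chromosome:
            raise FormatError(f"gene {self.gene_id}: empty chromosome")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CollinearityBlock:
    """One collinear (segmental-duplication) block of anchor gene pairs."""

    block_id: str
    anchor_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.anchor_pairs:
            raise FormatError(f"block {self.block_id}: no anchor pairs")
        for a, b in self.anchor_pairs:
            if a == b:
                raise FormatError(f"block {self.block_id}: self-pair {a}/{b}")

    def contains_pair(self, gene_a: str, gene_b: str) -> bool:
        pair = frozenset((gene_a, gene_b))
        return any(frozenset(p) == pair for p in self.anchor_pairs)


@dataclass(frozen=True)
class FixtureTables:
    """Transcriptions of the survey's three printed tables.

    ``table1``: species, lineage, predicted loci and family size for the
    17 genomes.  ``table2``: Ka, Ks, Ka/Ks and duplication type for ten
    selected paralog pairs.  ``table3``: per-species intact/degenerated/
    lack counts for the three NLS categories.  ``total_mismatch`` is True
    because the per-species family sizes sum to 435 while the stated
    family total is 434; the tables are stored exactly as printed.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    stated_total_genes: int = 434

    @property
    def total_mismatch(self) -> bool:
        return int(self.table1["aux_iaa_count"].sum()) != self.stated_total_genes


def _validate_residues(rec_id: str, molecule: str, residues: str) -> None:
    alphabet = PROTEIN_ALPHABET if molecule == "protein" else NUCLEOTIDE_ALPHABET
    bad = set(residues) - alphabet
    if bad:
        raise FormatError(
            f"record {rec_id!r}: illegal {molecule} characters {sorted(bad)}"
        )


def read_fasta(path: str | Path, molecule: Literal["protein", "cds"] = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are upper-cased; record order is preserved.  Empty files,
    duplicate ids and characters outside the molecule's alphabet raise
    :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        _validate_residues(rec.id, molecule, residues)
        records.append(SequenceRecord(rec.id, molecule, residues))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr_field.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (``gene`` + ``CDS`` features only).

    Coordinates are kept 1-based inclusive as in the file.  CDS features
    are linked to genes through their ``Parent`` attribute (directly or
    via an intermediate mRNA feature).  Genes without CDS children are
    returned with empty ``cds_ids`` and trigger a warning.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}
    cds_links: list[tuple[str, str]] = []  # (parent id, cds id)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                gene_id = attributes.get("ID")
                if not gene_id:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                if start > end:
                    raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
                genes[gene_id] = {
                    "chromosome": seqid,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "cds_ids": [],
                }
                gene_order.append(gene_id)
            elif ftype == "mRNA":
                mid = attributes.get("ID")
                parent = attributes.get("Parent")
                if mid and parent:
                    mrna_parent[mid] = parent
            elif ftype == "CDS":
                cds_id = attributes.get("ID")
                parent = attributes.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: CDS feature without Parent")
                cds_links.append((parent, cds_id or f"cds:{lineno}"))

    for parent, cds_id in cds_links:
        gene_id = mrna_parent.get(parent, parent)
        if gene_id in genes and cds_id not in genes[gene_id]["cds_ids"]:
            genes[gene_id]["cds_ids"].append(cds_id)

    models: list[GeneModel] = []
    for gene_id in gene_order:
        info = genes[gene_id]
        if not info["cds_ids"]:
            warnings.warn(f"gene {gene_id} has no CDS children", stacklevel=2)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=info["chromosome"],
                start=info["start"],
                end=info["end"],
                strand=info["strand"],
                cds_ids=tuple(info["cds_ids"]),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            fh.write(
                f"{gm.chromosome}\tauxiaa\tgene\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            for cds_id in gm.cds_ids:
                fh.write(
                    f"{gm.chromosome}\tauxiaa\tCDS\t{gm.start}\t{gm.end}\t.\t{gm.strand}\t0\tID={cds_id};Parent={gm.gene_id}\n"
                )


def read_collinearity_blocks(path: str | Path) -> list[CollinearityBlock]:
    """Read a tab-separated anchor-pair file (block_id, gene_a, gene_b).

    Pairs are grouped by block id with input order preserved; a self-pair
    line is rejected.  An empty file yields an empty list.
    """
    path = Path(path)
    pairs_by_block: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(cols)}"
                )
            block_id, gene_a, gene_b = cols
            if gene_a == gene_b:
                raise FormatError(f"{path}:{lineno}: self-pair {gene_a!r}")
            if block_id not in pairs_by_block:
                pairs_by_block[block_id] = []
                order.append(block_id)
            pairs_by_block[block_id].append((gene_a, gene_b))
    return [
        CollinearityBlock(block_id, tuple(pairs_by_block[block_id])) for block_id in order
    ]


def _data_path(name: str):
    return resources.files("auxiaa.data").joinpath(name)


def load_fixture_tables() -> FixtureTables:
    """Load the packaged transcriptions of the three printed survey tables."""
    with resources.as_file(_data_path("table1_gene_counts.tsv")) as p:
        t1 = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("table2_kaks_pairs.tsv")) as p:
        t2 = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path("table3_nls_counts.tsv")) as p:
        t3 = pd.read_csv(p, sep="\t")
    if len(t1) != 17 or len(t2) != 10 or len(t3) != 16:
        raise FormatError("packaged fixture tables have unexpected shapes")
    return FixtureTables(table1=t1, table2=t2, table3=t3)


def load_consensus_patterns() -> dict[str, str]:
    """Packaged consensus anchors for the five family motifs (``x`` = wildcard)."""
    with resources.as_file(_data_path("motif_consensus.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["motif_id"], df["pattern"]))
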