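"""Synthetic gene families with known ground truth.

Builds multi-gene families that look like a small Aux/IAA complement:
proteins carrying a chosen subset of the five family motifs in their
natural order (5–3–2–4–1 from the N terminus) with planted NLS
statuses, coding sequences back-translated from those proteins, gene
coordinates on synthetic chromosomes, tandem and segmental duplication
events with a truth log, and codon evolution under an MG94×HKY-style
process with chosen ω (Ka/Ks) and kappa (ts/tv).  Everything is
deterministic given the seed, and the emitted files use exactly the
formats the readers in :mod:`auxiaa.seqio` accept.

Linker (non-motif) residues are drawn from an alphabet disjoint from
every motif consensus and from K/R, so a planted motif or NLS status
can never be created or destroyed by linker chance; that is what makes
planted truth exactly recoverable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .codon import SENSE_CODONS, STOP_CODONS, is_transition, translate_codon
from .seqio import (
    CollinearityBlock,
    GeneModel,
    SequenceRecord,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "TruthEvent",
    "simulate_family",
    "evolve_codon_sequence",
    "simulate_divergent_pair",
    "plant_motifs_and_nls",
]

# Residues that cannot complete any motif consensus (even with the
# scanner's one allowed mismatch) nor any NLS pattern.
LINKER_ALPHABET = "ADEFHINQSTY"

MOTIF_SEQUENCES = {
    # concrete realizations of the consensus anchors, wildcards filled
    # with linker-safe residues
    "m5": "LALALA",      # domain I repression repeat (LxLxLx)
    "m3": "VGWPPV",      # domain II degron
    "m2": "VKVSM",       # domain III (VKVxM)
    "m4": "KRPRSSK",     # domain IV, doubles as the SV40-like NLS (KRxRxxK)
    "m1": "GDVPW",       # domain IV PB1 linker signature
}
# N-to-C order of the domains the motifs sit in
MOTIF_ORDER = ("m5", "m3", "m2", "m4", "m1")

NLS_SEQUENCES: dict[str, dict[str, str | None]] = {
    # planted realizations per target status
    "bipartite_part1": {"intact": "KR", "degenerated": "QR", "lack": None},
    # Part 2 sits in/next to domain II; degenerated form models the
    # documented first-arginine-to-cysteine substitution
    "bipartite_part2": {"intact": "RQQRK", "degenerated": "CQQRK", "lack": None},
    # the SV40 signal is the motif-4 sequence itself; degenerated form
    # substitutes the leading lysine
    "sv40": {"intact": "KRPRSSK", "degenerated": "QRPRSSK", "lack": None},
}

_BY_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _BY_AA.setdefault(translate_codon(_codon), []).append(_codon)

GENE_BP_SPACING = 200_000  # ancestral genes are placed far apart
TANDEM_GAP_RANGE = (1_000, 40_000)  # inside the 50-kb rule


class ConfigError(ValueError):
    """Impossible or contradictory simulation plan."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family.

    Rates are per gene per epoch; ``branch_length_syn`` is the expected
    number of synonymous substitutions per synonymous site each gene
    accumulates per epoch.  ``motif_plan`` maps gene index -> the set of
    motif ids the scaffold carries; ``nls_plan`` maps gene index ->
    {category: intact|degenerated|lack}.  Unlisted genes are canonical
    with all NLSs intact.
    """

    seed: int
    n_ancestral_genes: int = 6
    n_chromosomes: int = 3
    chromosome_length_bp: int = 5_000_000
    tandem_rate: float = 0.15
    segmental_rate: float = 0.10
    n_epochs: int = 2
    omega: float = 0.2
    kappa: float = 2.0
    branch_length_syn: float = 0.3
    gene_length_codons: int = 200
    motif_plan: Mapping[int, frozenset[str]] | None = None
    nls_plan: Mapping[int, Mapping[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.tandem_rate < 0 or self.segmental_rate < 0:
            raise ConfigError("duplication rates must be nonnegative")
        if self.omega < 0:
            raise ConfigError("omega must be nonnegative")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if self.n_chromosomes < 2 and self.segmental_rate > 0:
            raise ConfigError("segmental events need at least 2 chromosomes")
        if self.n_ancestral_genes < 1:
            raise ConfigError("need at least one ancestral gene")


@dataclass(frozen=True)
class TruthEvent:
    event_type: Literal["tandem", "segmental"]
    parent: str
    child: str
    epoch: int


@dataclass
class SimulatedFamily:
    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    gene_models: list[GeneModel]
    blocks: list[CollinearityBlock]
    truth_events: list[TruthEvent]
    true_omega: float
    true_kappa: float
    motif_truth: dict[str, frozenset[str]]
    nls_truth: dict[str, dict[str, str]]

    def protein_of(self, gene_id: str) -> str:
        for rec in self.proteins:
            if rec.id == gene_id:
                return rec.residues
        raise KeyError(gene_id)

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA/GFF3/collinearity TSV plus truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fa")
        write_fasta(self.cds, outdir / "cds.fa")
        write_gff3(self.gene_models, outdir / "genes.gff3")
        with (outdir / "collinearity.tsv").open("w") as fh:
            for block in self.blocks:
                for a, b in block.anchor_pairs:
                    fh.write(f"{block.block_id}\t{a}\t{b}\n")
        truth = {
            "events": [
                {
                    "type": e.event_type,
                    "parent": e.parent,
                    "child": e.child,
                    "epoch": e.epoch,
                }
                for e in self.truth_events
            ],
            "true_omega": self.true_omega,
            "true_kappa": self.true_kappa,
            "motif_truth": {g: sorted(v) for g, v in self.motif_truth.items()},
            "nls_truth": self.nls_truth,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

_NEIGHBORS: dict[str, list[tuple[str, bool, bool]]] = {}
for _c in SENSE_CODONS:
    lst = []
    for _pos in range(3):
        for _n in "ACGT":
            if _n == _c[_pos]:
                continue
            _alt = _c[:_pos] + _n + _c[_pos + 1 :]
            if _alt in STOP_CODONS:
                continue  # proposals creating stops are rejected
            lst.append(
                (
                    _alt,
                    is_transition(_c[_pos], _n),
                    translate_codon(_alt) == translate_codon(_c),
                )
            )
    _NEIGHBORS[_c] = lst


def _codon_rates(codon: str, omega: float, kappa: float) -> tuple[list[str], np.ndarray]:
    targets, rates = [], []
    for alt, ts, syn in _NEIGHBORS[codon]:
        rate = (kappa if ts else 1.0) * (1.0 if syn else omega)
        targets.append(alt)
        rates.append(rate)
    return targets, np.array(rates)


def _syn_scaling(codons: Sequence[str], kappa: float) -> float:
    """Time units per expected synonymous substitution per syn site.

    Synonymous sites are counted with kappa weighting (mutational
    opportunity, stops excluded); the synonymous flux is the kappa-
    weighted rate to synonymous neighbors.  The returned T makes the
    expected syn subs/syn site equal 1 for the given sequence.
    """
    flux = 0.0
    sites = 0.0
    for codon in codons:
        w_syn = w_all = 0.0
        for _, ts, syn in _NEIGHBORS[codon]:
            w = kappa if ts else 1.0
            w_all += w
            if syn:
                w_syn += w
        flux += w_syn
        if w_all > 0:
            sites += 3.0 * w_syn / w_all
    if flux == 0:
        raise ValueError("sequence has no synonymous mutational opportunity")
    return sites / flux


def evolve_codon_sequence(
    cds: str,
    t: float,
    omega: float,
    kappa: float,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a CDS for ``t`` expected synonymous subs per syn site.

    Continuous-time Gillespie simulation per codon under an MG94×HKY
    style process: single-nucleotide exchanges, transitions weighted by
    kappa, nonsynonymous exchanges by omega, proposals creating stop
    codons rejected.  Time is scaled on the input sequence so that the
    expected synonymous divergence matches ``t``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if len(cds) == 0 or len(cds) % 3:
        raise ValueError("CDS length must be a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if c in STOP_CODONS or c not in _NEIGHBORS:
            raise ValueError(f"invalid or stop codon {c!r} in CDS")
    if t == 0:
        return cds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = t * _syn_scaling(codons, kappa)
    out = []
    for codon in codons:
        clock = 0.0
        while True:
            targets, rates = _codon_rates(codon, omega, kappa)
            total = rates.sum()
            if total <= 0:
                break
            clock += rng.exponential(1.0 / total)
            if clock >= T:
                break
            codon = targets[int(rng.choice(len(targets), p=rates / total))]
        out.append(codon)
    return "".join(out)


def simulate_divergent_pair(
    n_codons: int,
    t: float,
    omega: float,
    kappa: float,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """An ancestral CDS evolved down two lineages of length t/2 each.

    The pair's expected synonymous divergence is ``t``; its true ω and
    kappa are the arguments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestor = "".join(rng.choice(SENSE_CODONS, size=n_codons))
    a = evolve_codon_sequence(ancestor, t / 2.0, omega, kappa, rng)
    b = evolve_codon_sequence(ancestor, t / 2.0, omega, kappa, rng)
    return a, b


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------


def _random_linker(rng: np.random.Generator, lo: int = 10, hi: int = 40) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(LINKER_ALPHABET), size=n))


def plant_motifs_and_nls(
    motif_sets: Sequence[frozenset[str] | set[str]],
    nls_statuses: Sequence[Mapping[str, str]] | None = None,
    seed: int | np.random.Generator = 0,
    min_length: int = 60,
) -> list[SequenceRecord]:
    """Protein scaffolds carrying requested motifs and NLS statuses.

    Motifs appear in their domain order (5, 3, 2, 4, 1) separated by
    random linkers from an alphabet that can never fake or break a
    motif or NLS.  NLS edits: Part 1 goes between motifs 5 and 3 (or the
    N-terminal third), Part 2 right next to motif 3 (or the middle
    third), and the SV40 signal rides on motif 4 itself: an intact
    signal is the motif-4 consensus, a degenerated one substitutes the
    leading lysine (still within the scanner's one-mismatch motif
    call), and "lack" requires the motif to be absent.  A plan
    combining an intact/degenerated SV40 with an absent motif 4 is
    contradictory and raises :class:`ConfigError`.  ``None`` entries in
    ``nls_statuses`` take the per-gene default (all intact, SV40
    following the motif set).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if nls_statuses is None:
        nls_statuses = [None] * len(motif_sets)
    if len(nls_statuses) != len(motif_sets):
        raise ConfigError("motif and NLS plans must have equal length")
    records = []
    for idx, (motifs, nls) in enumerate(zip(motif_sets, nls_statuses)):
        motifs = frozenset(motifs)
        unknown = motifs - set(MOTIF_ORDER)
        if unknown:
            raise ConfigError(f"unknown motif ids {sorted(unknown)}")
        if nls is None:
            # per-gene default: everything intact, except that the SV40
            # signal is the motif-4 consensus itself, so a scaffold
            # without motif 4 cannot carry it
            nls = {
                "bipartite_part1": "intact",
                "bipartite_part2": "intact",
                "sv40": "intact" if "m4" in motifs else "lack",
            }
        for cat, status in nls.items():
            if cat not in NLS_SEQUENCES or status not in ("intact", "degenerated", "lack"):
                raise ConfigError(f"invalid NLS plan entry {cat!r}={status!r}")
        if "m4" not in motifs and nls.get("sv40", "lack") != "lack":
            raise ConfigError(
                f"gene {idx}: an intact or degenerated SV40 NLS is the motif-4 "
                "consensus (within one mismatch); it cannot coexist with an "
                "absent motif 4"
            )

        part1 = NLS_SEQUENCES["bipartite_part1"][nls.get("bipartite_part1", "intact")]
        part2 = NLS_SEQUENCES["bipartite_part2"][nls.get("bipartite_part2", "intact")]
        sv40_status = nls.get("sv40", "intact")

        pieces = ["M", _random_linker(rng)]
        if "m5" in motifs:
            pieces.append(MOTIF_SEQUENCES["m5"])
        pieces.append(_random_linker(rng))
        if part1 is not None:
            pieces.append(part1)
            pieces.append(_random_linker(rng))
        if "m3" in motifs:
            pieces.append(MOTIF_SEQUENCES["m3"])
            if part2 is not None:
                pieces.append(part2)  # inside the motif-3 +/- 10 window
        elif part2 is not None:
            # no anchoring degron: the scanner will look in the middle
            # third, where this linker region falls for typical layouts
            pieces.append(part2)
        pieces.append(_random_linker(rng))
        if "m2" in motifs:
            pieces.append(MOTIF_SEQUENCES["m2"])
        pieces.append(_random_linker(rng))
        if "m4" in motifs:
            if sv40_status == "intact":
                pieces.append(MOTIF_SEQUENCES["m4"])
            elif sv40_status == "degenerated":
                pieces.append(NLS_SEQUENCES["sv40"]["degenerated"])
            else:
                raise ConfigError(
                    f"gene {idx}: cannot plant motif 4 while lacking the SV40 NLS "
                    "(the motif is the signal)"
                )
        # (m4 absent implies sv40 "lack"; enforced above)
        pieces.append(_random_linker(rng))
        if "m1" in motifs:
            pieces.append(MOTIF_SEQUENCES["m1"])
        pieces.append(_random_linker(rng))
        seq = "".join(pieces)
        while len(seq) < min_length:
            seq += _random_linker(rng)
        records.append(SequenceRecord(f"g{idx:03d}", "protein", seq))
    return records


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """A CDS translating to ``protein``, codons drawn uniformly."""
    codons = []
    for aa in protein:
        options = _BY_AA.get(aa)
        if options is None:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------


def _place_gene(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    chrom_len: int,
    gene_len: int,
    near: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Find a free interval, optionally within the tandem gap of ``near``."""
    for _ in range(200):
        if near is not None:
            gap = int(rng.integers(*TANDEM_GAP_RANGE))
            left = bool(rng.integers(2))
            start = near[0] - gap - gene_len if left else near[1] + gap
            if start < 1 or start + gene_len - 1 > chrom_len:
                continue
        else:
            start = int(rng.integers(1, chrom_len - gene_len))
        end = start + gene_len - 1
        if all(end < s or start > e for s, e in occupied):
            occupied.append((start, end))
            return start, end
    raise ConfigError("could not place gene: chromosome space exhausted")


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate one gene family with full ground truth.

    Ancestral genes are scaffolded from the motif/NLS plans, placed far
    apart on synthetic chromosomes and back-translated to CDS.  Each
    epoch, every gene may spawn a tandem copy (placed 1–40 kb away on
    the same chromosome) or a segmental copy (placed on a different
    chromosome and registered in a fresh collinearity block); then every
    CDS evolves by ``branch_length_syn`` expected synonymous
    substitutions per site under the configured codon model.  All
    duplications are recorded in the truth log.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ancestral_genes
    motif_plan = dict(config.motif_plan or {})
    nls_plan = dict(config.nls_plan or {})
    motif_sets = [
        frozenset(motif_plan.get(i, frozenset(MOTIF_ORDER))) for i in range(n)
    ]
    nls_statuses = [
        dict(nls_plan[i])
        if i in nls_plan
        else {
            "bipartite_part1": "intact",
            "bipartite_part2": "intact",
            "sv40": "intact" if "m4" in motif_sets[i] else "lack",
        }
        for i in range(n)
    ]
    scaffolds = plant_motifs_and_nls(motif_sets, nls_statuses, rng)

    cds_by_gene: dict[str, str] = {}
    motif_truth: dict[str, frozenset[str]] = {}
    nls_truth: dict[str, dict[str, str]] = {}
    models: dict[str, GeneModel] = {}
    occupied: dict[str, list[tuple[int, int]]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    for i, rec in enumerate(scaffolds):
        cds_by_gene[rec.id] = back_translate(rec.residues, rng)
        motif_truth[rec.id] = motif_sets[i]
        nls_truth[rec.id] = nls_statuses[i]
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        gene_len = 3 * len(rec.residues)
        start = 100_000 + GENE_BP_SPACING * (i // config.n_chromosomes) + 1
        end = start + gene_len - 1
        if end > config.chromosome_length_bp:
            raise ConfigError("chromosomes too short for the ancestral layout")
        occupied[chrom].append((start, end))
        models[rec.id] = GeneModel(rec.id, chrom, start, end, "+", (f"{rec.id}.cds",))

    events: list[TruthEvent] = []
    blocks: list[CollinearityBlock] = []
    counter = n
    for epoch in range(1, config.n_epochs + 1):
        for gene_id in list(models):
            parent = models[gene_id]
            if rng.random() < config.tandem_rate:
                child_id = f"g{counter:03d}"
                counter += 1
                gene_len = parent.length
                start, end = _place_gene(
                    rng,
                    occupied[parent.chromosome],
                    config.chromosome_length_bp,
                    gene_len,
                    near=(parent.start, parent.end),
                )
                models[child_id] = GeneModel(
                    child_id, parent.chromosome, start, end, "+", (f"{child_id}.cds",)
                )
                cds_by_gene[child_id] = cds_by_gene[gene_id]
                motif_truth[child_id] = motif_truth[gene_id]
                nls_truth[child_id] = dict(nls_truth[gene_id])
                events.append(TruthEvent("tandem", gene_id, child_id, epoch))
            if rng.random() < config.segmental_rate:
                child_id = f"g{counter:03d}"
                counter += 1
                others = [c for c in occupied if c != parent.chromosome]
                chrom = others[int(rng.integers(len(others)))]
                gene_len = parent.length
                start, end = _place_gene(
                    rng, occupied[chrom], config.chromosome_length_bp, gene_len
                )
                models[child_id] = GeneModel(
                    child_id, chrom, start, end, "+", (f"{child_id}.cds",)
                )
                cds_by_gene[child_id] = cds_by_gene[gene_id]
                motif_truth[child_id] = motif_truth[gene_id]
                nls_truth[child_id] = dict(nls_truth[gene_id])
                events.append(TruthEvent("segmental", gene_id, child_id, epoch))
                blocks.append(
                    CollinearityBlock(
                        f"block{len(blocks) + 1}", ((gene_id, child_id),)
                    )
                )
        if config.branch_length_syn > 0:
            for gene_id in list(cds_by_gene):
                cds_by_gene[gene_id] = evolve_codon_sequence(
                    cds_by_gene[gene_id],
                    config.branch_length_syn,
                    config.omega,
                    config.kappa,
                    rng,
                )

    gene_ids = sorted(models)
    proteins = [
        SequenceRecord(
            g,
            "protein",
            "".join(
                translate_codon(cds_by_gene[g][i : i + 3])
                for i in range(0, len(cds_by_gene[g]), 3)
            ),
        )
        for g in gene_ids
    ]
    cds = [SequenceRecord(g, "cds", cds_by_gene[g]) for g in gene_ids]
    return SimulatedFamily(
        proteins=proteins,
        cds=cds,
        gene_models=[models[g] for g in gene_ids],
        blocks=blocks,
        truth_events=events,
        true_omega=config.omega,
        true_kappa=config.kappa,
        motif_truth=motif_truth,
        nls_truth=nls_truth,
    )
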