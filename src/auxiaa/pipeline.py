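"""End-to-end orchestration: motifs → typing → NLS → duplication →
Ka/Ks → tree → statistics, from a single YAML config.

Every stage writes a TSV (or Newick/JSON) into the output directory and
a manifest records the seed, thresholds and per-stage wall time, so a
rerun with identical inputs and seed reproduces identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .classify import classify_pb1_signature, classify_type, summarize_types
from .codon import (
    align_proteins_global,
    estimate_kaks_myn,
    estimate_kaks_ng86,
    omega_ratio,
    project_to_codons,
)
from .duplication import (
    assign_segmental,
    candidate_pairs,
    duplication_summary,
    pairs_table,
)
from .motifs import call_presence, default_consensus_models
from .nls import aggregate_species, scan_protein
from .phylogeny import bootstrap_support, extract_sister_pairs, to_newick
from .seqio import (
    read_collinearity_blocks,
    read_fasta,
    read_gff3,
)
from .stats import students_t_test

logger = logging.getLogger("auxiaa")

STAGES = ("motifs", "classify", "nls", "duplication", "kaks", "tree", "stats")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved."""


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and thresholds for one pipeline run."""

    protein_fasta: str | None = None
    cds_fasta: str | None = None
    gff3: str | None = None
    collinearity: str | None = None
    species_map: str | None = None  # TSV: sequence_id <tab> species
    msa_fasta: str | None = None  # aligned FASTA for the tree stage
    stages: tuple[str, ...] = STAGES
    threshold_fraction: float = 0.6
    identity_min: float = 50.0
    max_distance: int = 50_000
    bootstrap_replicates: int = 1000
    sister_min_support: float = 90.0
    kaks_method: str = "MYN"
    seed: int = 0
    outdir: str = "auxiaa_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Findings as (level, message); any "error" blocks execution."""
    findings: list[tuple[str, str]] = []
    err = lambda m: findings.append(("error", m))
    warn = lambda m: findings.append(("warning", m))

    for stage in config.stages:
        if stage not in STAGES:
            err(f"unknown stage {stage!r}")
    if not (0 < config.threshold_fraction <= 1):
        err(f"threshold_fraction {config.threshold_fraction} outside (0, 1]")
    if not (0 <= config.identity_min <= 100):
        err(f"identity_min {config.identity_min} outside [0, 100]")
    if config.max_distance <= 0:
        err("max_distance must be positive")
    if config.kaks_method not in ("MYN", "NG86"):
        err(f"unknown kaks_method {config.kaks_method!r}")
    if not (0 <= config.sister_min_support <= 100):
        err("sister_min_support outside [0, 100]")

    needs_proteins = {"motifs", "classify", "nls", "duplication", "kaks"}
    if needs_proteins & set(config.stages) and config.protein_fasta is None:
        err("protein_fasta required for the enabled stages")
    if "duplication" in config.stages and config.gff3 is None:
        err("gff3 required for the duplication stage")
    if "kaks" in config.stages and config.cds_fasta is None:
        err("cds_fasta required for the kaks stage")
    if "tree" in config.stages:
        if config.bootstrap_replicates < 1:
            err("bootstrap_replicates must be >= 1 when the tree stage is on")
        if config.msa_fasta is None and config.protein_fasta is None:
            err("tree stage needs msa_fasta (or an equal-length protein_fasta)")
    for name in ("protein_fasta", "cds_fasta", "gff3", "collinearity",
                 "species_map", "msa_fasta"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            err(f"{name} path {p!r} does not exist")
    if "duplication" in config.stages and config.collinearity is None:
        warn("no collinearity file: no segmental calls will be made")
    return findings


def _read_species_map(path: str | None, default_ids: list[str]) -> dict[str, str]:
    if path is None:
        return {i: "unassigned" for i in default_ids}
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, species = line.split("\t")[:2]
            out[seq_id] = species
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in order and write the report bundle.

    Returns the manifest.  A stage failure raises
    :class:`PipelineError` naming the stage; outputs of earlier stages
    stay on disk.
    """
    findings = validate_config(config)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise PipelineError("config invalid: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "threshold_fraction": config.threshold_fraction,
            "identity_min": config.identity_min,
            "max_distance": config.max_distance,
            "bootstrap_replicates": config.bootstrap_replicates,
            "sister_min_support": config.sister_min_support,
            "kaks_method": config.kaks_method,
        },
        "stages": {},
    }

    proteins = None
    if config.protein_fasta:
        proteins = read_fasta(config.protein_fasta, "protein")
    profiles = {}
    classified = []
    state: dict[str, Any] = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        try:
            if stage == "motifs":
                models = default_consensus_models()
                profiles = {
                    p.id: call_presence(p, models, config.threshold_fraction)
                    for p in proteins
                }
                rows = [
                    {"sequence_id": sid, **{m: prof.present[m] for m in sorted(prof.present)}}
                    for sid, prof in profiles.items()
                ]
                pd.DataFrame(rows).to_csv(
                    outdir / "motif_presence.tsv", sep="\t", index=False
                )
            elif stage == "classify":
                if not profiles:
                    models = default_consensus_models()
                    profiles = {
                        p.id: call_presence(p, models, config.threshold_fraction)
                        for p in proteins
                    }
                classified = [classify_type(profiles[p.id]) for p in proteins]
                pb1 = {p.id: classify_pb1_signature(p).signature for p in proteins}
                pd.DataFrame(
                    [
                        {
                            "sequence_id": a.sequence_id,
                            "type": a.type_label,
                            "canonical": a.canonical,
                            "pb1_signature": pb1[a.sequence_id],
                        }
                        for a in classified
                    ]
                ).to_csv(outdir / "types.tsv", sep="\t", index=False)
                summarize_types(classified).to_csv(
                    outdir / "type_summary.tsv", sep="\t", index=False
                )
            elif stage == "nls":
                if not profiles:
                    models = default_consensus_models()
                    profiles = {
                        p.id: call_presence(p, models, config.threshold_fraction)
                        for p in proteins
                    }
                species_of = _read_species_map(
                    config.species_map, [p.id for p in proteins]
                )
                reports = [
                    scan_protein(p, profiles[p.id], species_of.get(p.id))
                    for p in proteins
                ]
                pd.DataFrame(
                    [
                        {
                            "sequence_id": c.sequence_id,
                            "category": c.category,
                            "status": c.status,
                            "window_start": c.window_start,
                            "matched": c.matched,
                            "variant_tag": c.variant_tag,
                        }
                        for r in reports
                        for c in r.calls
                    ]
                ).to_csv(outdir / "nls_report.tsv", sep="\t", index=False)
                summaries, overall = aggregate_species(reports, species_of)
                overall.to_csv(outdir / "nls_overall.tsv", sep="\t", index=False)
                state["nls_overall"] = overall
            elif stage == "duplication":
                gene_models = read_gff3(config.gff3)
                prot_map = {p.id: p.residues for p in proteins}
                pairs = candidate_pairs(
                    gene_models,
                    prot_map,
                    identity_min=config.identity_min,
                    max_distance=config.max_distance,
                )
                blocks = (
                    read_collinearity_blocks(config.collinearity)
                    if config.collinearity
                    else []
                )
                pairs = assign_segmental(pairs, blocks)
                state["pairs"] = pairs
                pairs_table(pairs).to_csv(
                    outdir / "duplication_pairs.tsv", sep="\t", index=False
                )
                species_of = _read_species_map(
                    config.species_map, [g.gene_id for g in gene_models]
                )
                summary = duplication_summary(
                    pairs, [g.gene_id for g in gene_models], species_of
                )
                pd.DataFrame(
                    [
                        {
                            "species": s.species,
                            "Seg": s.seg,
                            "Tan": s.tan,
                            "Seg&Tan": s.seg_and_tan,
                            "Total": s.total,
                            "Seg%": s.seg_pct,
                            "Tan%": s.tan_pct,
                        }
                        for s in summary
                    ]
                ).to_csv(outdir / "duplication_summary.tsv", sep="\t", index=False)
            elif stage == "kaks":
                cds = {r.id: r.residues for r in read_fasta(config.cds_fasta, "cds")}
                prot_map = {p.id: p.residues for p in proteins}
                pairs = state.get("pairs", [])
                dup_pairs = [
                    p for p in pairs if p.classification in ("tandem", "segmental", "both")
                ]
                estimator = (
                    estimate_kaks_myn if config.kaks_method == "MYN" else estimate_kaks_ng86
                )
                rows = []
                results = []
                for p in dup_pairs:
                    label = f"{p.gene_a}/{p.gene_b}"
                    aln = align_proteins_global(
                        prot_map[p.gene_a], prot_map[p.gene_b]
                    )
                    codon_aln = project_to_codons(aln, cds[p.gene_a], cds[p.gene_b])
                    res = estimator(codon_aln, pair=label)
                    results.append((p.classification, res))
                    rows.append(
                        {
                            "pair": label,
                            "ka": None if res.ka is None else round(res.ka, 4),
                            "ks": None if res.ks is None else round(res.ks, 4),
                            "ka_ks": None
                            if res.ka is None or res.ks is None or res.ks == 0
                            else omega_ratio(res.ka, res.ks),
                            "method": res.method,
                            "duplication_type": p.classification,
                        }
                    )
                state["kaks"] = results
                pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
            elif stage == "tree":
                msa_path = config.msa_fasta or config.protein_fasta
                msa = read_fasta(msa_path, "protein")
                lengths = {len(r.residues) for r in msa}
                if len(lengths) > 1:
                    raise PipelineError(
                        "tree stage needs equal-length (aligned) sequences; "
                        "supply msa_fasta"
                    )
                tree = bootstrap_support(
                    msa, replicates=config.bootstrap_replicates, seed=config.seed
                )
                (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
                sisters = extract_sister_pairs(tree, config.sister_min_support)
                pd.DataFrame(
                    [
                        {"taxon_a": s.taxon_a, "taxon_b": s.taxon_b, "support": s.support}
                        for s in sisters
                    ]
                ).to_csv(outdir / "sister_pairs.tsv", sep="\t", index=False)
            elif stage == "stats":
                out: dict[str, Any] = {}
                results = state.get("kaks", [])
                seg = [
                    r.omega
                    for cls, r in results
                    if cls in ("segmental", "both") and r.omega is not None
                ]
                tan = [
                    r.omega
                    for cls, r in results
                    if cls in ("tandem", "both") and r.omega is not None
                ]
                if seg:
                    out["mean_omega_segmental"] = round(sum(seg) / len(seg), 4)
                if tan:
                    out["mean_omega_tandem"] = round(sum(tan) / len(tan), 4)
                if len(seg) >= 2 and len(tan) >= 2:
                    t = students_t_test(seg, tan)
                    out["seg_vs_tan_t"] = t.estimate
                    out["seg_vs_tan_p"] = t.p_value
                (outdir / "stats.json").write_text(json.dumps(out, indent=2))
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3)
        }
        logger.info("stage %s done", stage)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
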