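import numpy as np
import pytest

from auxiaa.classify import classify_type
from auxiaa.codon import CodonAlignment, estimate_kaks_ng86, translate_codon
from auxiaa.duplication import assign_segmental, candidate_pairs
from auxiaa.motifs import call_presence
from auxiaa.seqio import read_fasta, read_gff3, read_collinearity_blocks
from auxiaa.simulate import (
    ConfigError,
    SimulationConfig,
    evolve_codon_sequence,
    plant_motifs_and_nls,
    simulate_divergent_pair,
    simulate_family,
)

ALL5 = frozenset({"m1", "m2", "m3", "m4", "m5"})


def split(cds):
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


class TestCodonEvolution:
    def test_zero_time_identity(self):
        cds = "ATGAAATTTGGG"
        assert evolve_codon_sequence(cds, 0.0, 0.5, 2.0, seed=1) == cds

    def test_omega_zero_preserves_protein(self):
        rng = np.random.default_rng(2)
        from auxiaa.codon import SENSE_CODONS

        cds = "".join(rng.choice(SENSE_CODONS, size=500))
        out = evolve_codon_sequence(cds, 0.3, 0.0, 2.0, seed=3)
        prot_in = [translate_codon(c) for c in split(cds)]
        prot_out = [translate_codon(c) for c in split(out)]
        assert prot_in == prot_out
        r = estimate_kaks_ng86(CodonAlignment(tuple(zip(split(cds), split(out)))))
        assert r.ka == 0.0

    def test_invalid_cds_rejected(self):
        with pytest.raises(ValueError):
            evolve_codon_sequence("ATGA", 0.1, 0.5, 2.0)
        with pytest.raises(ValueError):
            evolve_codon_sequence("TAAATG", 0.1, 0.5, 2.0)

    def test_divergence_calibration(self):
        # realized synonymous divergence tracks the requested t
        t = 0.3
        ks = []
        rng = np.random.default_rng(11)
        for _ in range(30):
            a, b = simulate_divergent_pair(400, t, 0.2, 2.0, seed=rng)
            r = estimate_kaks_ng86(CodonAlignment(tuple(zip(split(a), split(b)))))
            ks.append(r.ks)
        # NG86's equal-weight site counting under kappa=2 biases Ks up a
        # little; the mean must still sit within 15% of the target
        assert abs(float(np.mean(ks)) - t) / t < 0.15

    def test_omega_recovery_at_half(self):
        rng = np.random.default_rng(21)
        omegas = []
        for _ in range(25):
            a, b = simulate_divergent_pair(500, 0.4, 0.5, 2.0, seed=rng)
            r = estimate_kaks_ng86(CodonAlignment(tuple(zip(split(a), split(b)))))
            omegas.append(r.omega)
        assert abs(float(np.median(omegas)) - 0.5) / 0.5 < 0.2


class TestScaffolds:
    def test_canonical_plan_realized(self):
        (rec,) = plant_motifs_and_nls([ALL5], seed=1)
        assert classify_type(call_presence(rec)).type_label == "I"

    def test_type_viii_plan_realized(self):
        (rec,) = plant_motifs_and_nls([frozenset({"m1", "m2"})], seed=2)
        assert classify_type(call_presence(rec)).type_label == "VIII"

    def test_contradictory_sv40_plan_rejected(self):
        with pytest.raises(ConfigError):
            plant_motifs_and_nls(
                [ALL5],
                [{"bipartite_part1": "intact", "bipartite_part2": "intact",
                  "sv40": "lack"}],
                seed=3,
            )

    def test_unknown_motif_rejected(self):
        with pytest.raises(ConfigError):
            plant_motifs_and_nls([frozenset({"m9"})], seed=1)


class TestFamilySimulation:
    def test_no_duplication_rates_no_events(self):
        fam = simulate_family(
            SimulationConfig(seed=1, tandem_rate=0.0, segmental_rate=0.0, n_epochs=3)
        )
        assert fam.truth_events == []
        assert len(fam.gene_models) == len(fam.proteins) == 6

    def test_seed_repeatability_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=77, n_epochs=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_family(cfg).write(d1)
        simulate_family(cfg).write(d2)
        for name in ("proteins.fa", "cds.fa", "genes.gff3", "collinearity.tsv",
                     "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_emitted_files_readable_by_io_layer(self, tmp_path):
        fam = simulate_family(SimulationConfig(seed=5))
        fam.write(tmp_path)
        prots = read_fasta(tmp_path / "proteins.fa", "protein")
        cds = read_fasta(tmp_path / "cds.fa", "cds")
        models = read_gff3(tmp_path / "genes.gff3")
        read_collinearity_blocks(tmp_path / "collinearity.tsv")
        assert {p.id for p in prots} == {m.gene_id for m in models}
        assert {c.id for c in cds} == {p.id for p in prots}

    def test_truth_log_consistent_with_coordinates(self):
        fam = simulate_family(SimulationConfig(seed=9, tandem_rate=0.4,
                                               segmental_rate=0.3, n_epochs=2))
        models = {m.gene_id: m for m in fam.gene_models}
        anchored = {
            frozenset(p) for b in fam.blocks for p in b.anchor_pairs
        }
        for ev in fam.truth_events:
            parent, child = models[ev.parent], models[ev.child]
            if ev.event_type == "tandem":
                assert parent.chromosome == child.chromosome
                gap = max(child.start - parent.end, parent.start - child.end)
                assert 0 < gap <= 50_000
            else:
                assert parent.chromosome != child.chromosome
                assert frozenset((ev.parent, ev.child)) in anchored

    def test_planted_tandem_events_recovered_end_to_end(self):
        fam = simulate_family(SimulationConfig(seed=13, tandem_rate=0.5,
                                               segmental_rate=0.0, n_epochs=1))
        tandem_truth = {
            frozenset((e.parent, e.child))
            for e in fam.truth_events
            if e.event_type == "tandem"
        }
        assert tandem_truth  # the configuration does produce events
        pairs = candidate_pairs(fam.gene_models, fam.proteins)
        called = {
            frozenset((p.gene_a, p.gene_b))
            for p in pairs
            if p.classification == "tandem"
        }
        assert tandem_truth <= called

    def test_impossible_layout_rejected(self):
        with pytest.raises(ConfigError):
            simulate_family(
                SimulationConfig(
                    seed=1,
                    n_ancestral_genes=40,
                    n_chromosomes=2,
                    chromosome_length_bp=120_000,
                )
            )
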