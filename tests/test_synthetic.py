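"""Synthetic generator: templates, planted truth, determinism, cohorts."""

import numpy as np
import pytest

from tdnakit.structure import partition_cloverleaf
from tdnakit.synthetic import (
    GeneSpec,
    GenomeConfig,
    TruthManifest,
    build_trna_template,
    mirror_genome,
    simulate_paired_alignment,
    synthesize_cohort,
    synthesize_genome,
)


class TestTemplate:
    def test_canonical_geometry(self):
        gene, ss = build_trna_template("Ala", "AGC", 0, seed=1)
        assert len(gene) == 72
        part = partition_cloverleaf(ss)
        assert part.stem_lengths == {"acceptor": 7, "D": 4,
                                     "anticodon": 5, "T": 5}
        assert len(part.loops["variable"]) == 4

    def test_anticodon_placed_at_34_36(self):
        gene, _ = build_trna_template("Ala", "AGC", 0, seed=1)
        assert gene[33:36] == "AGC"

    def test_intron_inserted_after_position_37(self):
        gene, _ = build_trna_template("eMet", "CAT", 12, seed=3)
        assert len(gene) == 84
        intron = gene[37:49]
        assert intron.startswith("GCT") and intron.endswith("GAGT")
        # splicing the intron back out recovers the 72-nt mature gene
        mature, _ = build_trna_template("eMet", "CAT", 0, seed=3)
        assert gene[:37] + gene[49:] == mature

    def test_short_intron_rejected(self):
        with pytest.raises(ValueError):
            build_trna_template("Ala", "AGC", 5, seed=1)

    def test_backbone_fixed_per_isotype(self):
        g1, _ = build_trna_template("Ala", "AGC", 0, seed=9)
        g2, _ = build_trna_template("Ala", "TGC", 0, seed=9)
        diff = [i for i, (a, b) in enumerate(zip(g1, g2)) if a != b]
        assert set(diff) <= {33, 34, 35}


class TestGenomeSynthesis:
    def test_tandem_layout_yields_one_expected_cluster(self):
        cfg = GenomeConfig(contig_lengths={"c": 40_000}, gene_specs=[
            GeneSpec("Pro", "TGG", copy_number=3, layout="tandem",
                     spacer_bp=100)])
        _, records, manifest = synthesize_genome(cfg, seed=11)
        assert len(records) == 3
        assert len(manifest.clusters) == 1
        c = manifest.clusters[0]
        assert len(c["members"]) == 3
        assert c["pattern"] == "homogeneous:Pro"

    def test_alternating_layout_pattern(self):
        cfg = GenomeConfig(contig_lengths={"c": 40_000}, gene_specs=[
            GeneSpec("Tyr", "GTA", copy_number=4, layout="alternating",
                     partner=GeneSpec("Ser", "AGA"), spacer_bp=80)])
        _, records, manifest = synthesize_genome(cfg, seed=11)
        assert len(records) == 8
        (c,) = manifest.clusters
        assert len(c["members"]) == 8
        assert c["pattern"] == "alternating:Tyr/Ser"

    def test_planted_t_runs_recorded_as_terminator_and_backup(self):
        cfg = GenomeConfig(contig_lengths={"c": 20_000}, gene_specs=[
            GeneSpec("Ala", "AGC", downstream_t_runs=((5, 3), (4, 20)))])
        _, _, manifest = synthesize_genome(cfg, seed=2)
        (g,) = manifest.genes
        assert g.t_runs == [(3, 5), (20, 4)]

    def test_minus_strand_gene_sequence_is_sense(self, planted):
        genome, records, _ = planted
        for rec in records:
            assert genome.fetch(rec.locus) == rec.gene_sequence

    def test_same_seed_identical_different_seed_differs(self):
        cfg = GenomeConfig(contig_lengths={"c": 30_000}, gene_specs=[
            GeneSpec("Ala", "AGC", copy_number=2)])
        g1, r1, m1 = synthesize_genome(cfg, seed=5)
        g2, r2, m2 = synthesize_genome(cfg, seed=5)
        g3, _, _ = synthesize_genome(cfg, seed=6)
        assert g1.contigs == g2.contigs
        assert [r.locus for r in r1] == [r.locus for r in r2]
        assert g1.contigs != g3.contigs

    def test_overfull_contig_raises(self):
        cfg = GenomeConfig(contig_lengths={"c": 3_000}, gene_specs=[
            GeneSpec("Ala", "AGC", copy_number=10)])
        with pytest.raises(RuntimeError, match="cannot place"):
            synthesize_genome(cfg, seed=1)

    def test_manifest_round_trips_through_json(self, tmp_path, manifest):
        p = tmp_path / "truth.json"
        manifest.to_json(p)
        back = TruthManifest.from_json(p)
        assert back.clusters == manifest.clusters
        assert back.unique_fraction_pct == manifest.unique_fraction_pct
        assert [g.gene_id for g in back.genes] == \
            [g.gene_id for g in manifest.genes]

    def test_mirror_preserves_sense_sequences(self, planted):
        genome, records, _ = planted
        mirrored, mrecords = mirror_genome(genome, records)
        for rec, mrec in zip(records, mrecords):
            assert mirrored.fetch(mrec.locus) == rec.gene_sequence
            assert mrec.locus.strand != rec.locus.strand


class TestSpecValidation:
    def test_motif_outside_window_rejected(self):
        with pytest.raises(ValueError):
            GeneSpec("Ala", "AGC", upstream_motifs=(("TATA", 60),))

    def test_t_run_outside_window_rejected(self):
        with pytest.raises(ValueError):
            GeneSpec("Ala", "AGC", downstream_t_runs=((10, 45),))

    def test_alternating_needs_partner(self):
        with pytest.raises(ValueError):
            GeneSpec("Tyr", "GTA", layout="alternating")


class TestCohort:
    def test_noiseless_counts_follow_the_line(self):
        cohort = synthesize_cohort(n_genomes=10, size_range_mb=(0.1, 1.0),
                                   slope=100, intercept=5, noise_sd=0,
                                   seed=3)
        for g in cohort.genomes:
            expected = round(5 + 100 * g.size_mb)
            assert cohort.counts[g.genome_id] == max(1, expected)

    def test_counts_reproducible_bit_identically(self):
        a = synthesize_cohort(n_genomes=50, noise_sd=20, seed=8)
        b = synthesize_cohort(n_genomes=50, noise_sd=20, seed=8)
        assert a.counts == b.counts

    def test_degenerate_size_range_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cohort(n_genomes=5, size_range_mb=(0.2, 0.2),
                              noise_sd=0, seed=1)

    def test_materialized_cohort_has_sequences_and_shared_gene(self):
        cohort = synthesize_cohort(
            n_genomes=3, size_range_mb=(0.04, 0.06), slope=200,
            intercept=5, noise_sd=0, seed=4, materialize=True)
        seq_sets = []
        for g in cohort.genomes:
            assert g.contigs is not None
            recs = cohort.records[g.genome_id]
            assert len(recs) == cohort.counts[g.genome_id]
            seq_sets.append({r.gene_sequence for r in recs})
        shared = set.intersection(*seq_sets)
        assert shared  # the planted Ala-AGC gene is identical everywhere


class TestAlignmentSimulators:
    def test_compensatory_rows_always_pairable(self):
        pairs = [(0, 9), (1, 8)]
        rows = simulate_paired_alignment(20, 10, pairs, "compensatory",
                                         seed=5)
        ok = {"AT", "TA", "GC", "CG", "GT", "TG"}
        for _, seq in rows:
            for i, j in pairs:
                assert seq[i] + seq[j] in ok

    def test_modes_differ_and_are_seeded(self):
        pairs = [(0, 5)]
        a = simulate_paired_alignment(5, 6, pairs, "independent", seed=1)
        b = simulate_paired_alignment(5, 6, pairs, "independent", seed=1)
        assert a == b
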