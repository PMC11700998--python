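"""Flank extraction and TATA/CAA/poly(T) scans vs naive string oracles."""

import numpy as np
import pytest

from tdnakit.flanks import (
    FlankSet,
    aggregate_flank_reports,
    build_flank_report,
    composition_profile,
    extract_flanks,
    genome_at_baseline,
    scan_caa,
    scan_polyt,
    scan_tata,
)
from tdnakit.io_formats import GeneLocus, GenomeRecord, TRNAGeneRecord, \
    revcomp
from tdnakit.synthetic import mirror_genome


def flankset(up="", down=""):
    return FlankSet("g", upstream50=up, upstream300=up, downstream50=down)


class TestExtraction:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.seq = "".join(rng.choice(list("ACGT"), size=600))
        self.genome = GenomeRecord("g", contigs={"c": self.seq})

    def test_plus_strand_windows(self):
        rec = TRNAGeneRecord("g1", GeneLocus("c", 350, 422), "Ala", "AGC")
        fs = extract_flanks(rec, self.genome)
        assert fs.upstream50 == self.seq[300:350]
        assert fs.upstream300 == self.seq[50:350]
        assert fs.downstream50 == self.seq[422:472]
        assert not fs.truncated

    def test_minus_strand_windows_are_mirrored(self):
        rec = TRNAGeneRecord("g1", GeneLocus("c", 100, 172, "-"), "Ala",
                             "AGC")
        fs = extract_flanks(rec, self.genome)
        assert fs.upstream50 == revcomp(self.seq[172:222])
        assert fs.downstream50 == revcomp(self.seq[50:100])

    def test_contig_edge_truncates_and_flags(self):
        rec = TRNAGeneRecord("g1", GeneLocus("c", 10, 82), "Ala", "AGC")
        fs = extract_flanks(rec, self.genome)
        assert len(fs.upstream50) == 10
        assert fs.truncated

    def test_locus_outside_contig_raises(self):
        rec = TRNAGeneRecord("g1", GeneLocus("zz", 0, 72), "Ala", "AGC")
        with pytest.raises(ValueError):
            extract_flanks(rec, self.genome)


class TestScans:
    def test_overlapping_tata_counts_twice(self):
        count, cat = scan_tata("GGTATATAGG")
        assert (count, cat) == (2, "2")

    @pytest.mark.parametrize("window,expected", [
        ("GGGGCCCC", (0, "0")),
        ("GTATAG", (1, "1")),
        ("TATAGGTATAGGTATA", (3, ">2")),
    ])
    def test_tata_categories(self, window, expected):
        assert scan_tata(window) == expected

    def test_caa_windows(self):
        up = "G" * 38 + "CAACAACAACAA"  # CAA at -12,-9,-6,-3
        c50, c10 = scan_caa(flankset(up=up))
        assert c50 == 4
        assert c10 == 3  # the -10 window sees the CAAs at -9, -6, -3

    @pytest.mark.parametrize("up,expected", [
        ("CAAA" + "G" * 46, 1),
        ("CACACA" + "G" * 44, 0),
    ])
    def test_caa_edge_patterns(self, up, expected):
        assert scan_caa(flankset(up=up))[0] == expected

    def test_polyt_terminator(self):
        runs = scan_polyt(flankset(down="AATTTTTAA" + "G" * 41))
        assert [(r.offset, r.length, r.role) for r in runs] == \
            [(2, 5, "terminator")]

    def test_polyt_backup(self):
        runs = scan_polyt(flankset(down="TTTTAATTTTA" + "G" * 39))
        assert [(r.length, r.role) for r in runs] == \
            [(4, "terminator"), (4, "backup")]

    def test_run_below_threshold_ignored(self):
        assert scan_polyt(flankset(down="TTTAAA" + "G" * 44)) == []

    def test_run_truncated_by_window_edge_flagged(self):
        runs = scan_polyt(flankset(down="G" * 44 + "TTTTTT"))
        assert runs[0].truncated

    def test_scans_match_naive_oracle_on_random_windows(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            w = "".join(rng.choice(list("ACGT"), size=50))
            # TATA oracle
            naive_tata = sum(w[p:p + 4] == "TATA" for p in range(47))
            assert scan_tata(w)[0] == naive_tata
            # CAA oracle
            naive_caa = sum(w[p:p + 3] == "CAA" for p in range(48))
            assert scan_caa(flankset(up=w))[0] == naive_caa
            # poly(T) oracle via regex-free grouping
            runs, i = [], 0
            while i < 50:
                if w[i] == "T":
                    j = i
                    while j < 50 and w[j] == "T":
                        j += 1
                    if j - i >= 4:
                        runs.append((i, j - i))
                    i = j
                else:
                    i += 1
            got = [(r.offset, r.length)
                   for r in scan_polyt(flankset(down=w))]
            assert got == runs


class TestPlantedTruth:
    def test_per_gene_counts_equal_manifest(self, planted):
        genome, records, manifest = planted
        truth = {g.gene_id: g for g in manifest.genes}
        for rec in records:
            report = build_flank_report(extract_flanks(rec, genome))
            g = truth[rec.gene_id]
            assert report.tata_count == g.tata_count
            assert report.caa_count_50 == g.caa_50
            assert report.caa_count_10 == g.caa_10
            assert [(r.offset, r.length) for r in report.polyt_runs] == \
                [tuple(t) for t in g.t_runs]

    def test_strand_mirror_gives_identical_reports(self, planted):
        genome, records, _ = planted
        mirrored, mrecords = mirror_genome(genome, records)

        def report_tuple(rec, gnm):
            r = build_flank_report(extract_flanks(rec, gnm))
            return (r.gene_id, r.tata_count, r.caa_count_50, r.caa_count_10,
                    [(p.offset, p.length) for p in r.polyt_runs])

        a = sorted(report_tuple(r, genome) for r in records)
        b = sorted(report_tuple(r, mirrored) for r in mrecords)
        assert a == b


class TestComposition:
    def test_all_a_windows(self):
        fs = [flankset(up="A" * 50) for _ in range(5)]
        prof = composition_profile(fs, "upstream50")
        assert np.allclose(prof["at_fraction"], 1.0)
        assert np.allclose(prof["information_bits"], 2.0)

    def test_uniform_windows_approach_half_at(self):
        rng = np.random.default_rng(3)
        n = 4000
        fs = [flankset(up="".join(rng.choice(list("ACGT"), size=50)))
              for _ in range(n)]
        prof = composition_profile(fs, "upstream50")
        sigma = 0.5 / np.sqrt(n)
        assert np.all(np.abs(prof["at_fraction"] - 0.5) < 3.5 * sigma + 0.02)

    def test_planted_at_rich_exceeds_baseline(self):
        rng = np.random.default_rng(4)
        rich = [flankset(up="".join(
            rng.choice(list("ACGT"), size=50, p=[0.4, 0.1, 0.1, 0.4])))
            for _ in range(300)]
        prof = composition_profile(rich, "upstream50")
        baseline = genome_at_baseline(
            GenomeRecord("g", contigs={
                "c": "".join(rng.choice(list("ACGT"), size=20_000))}))
        assert np.all(prof["at_fraction"] > baseline)

    def test_all_truncated_raises(self):
        fs = [FlankSet("g", "A" * 10, "A" * 10, "A" * 10, truncated=True)]
        with pytest.raises(ValueError):
            composition_profile(fs)


class TestAggregate:
    def test_survey_shaped_summary(self):
        reports = [
            build_flank_report(flankset(up="G" * 30 + "TATA" + "G" * 16,
                                        down="AATTTTA" + "G" * 43)),
            build_flank_report(flankset(up="G" * 47 + "CAA",
                                        down="TTTTTGGTTTT" + "G" * 39)),
            build_flank_report(flankset(up="G" * 50, down="G" * 50)),
        ]
        agg = aggregate_flank_reports(reports)
        assert agg["n_tdnas"] == 3
        assert agg["pct_tata_ge1"] == pytest.approx(100 / 3)
        assert agg["pct_caa_10"] == pytest.approx(100 / 3)
        assert agg["pct_polyt"] == pytest.approx(200 / 3)
        assert agg["pct_backup_polyt"] == pytest.approx(100 / 3)
        assert agg["mean_terminator_len"] == pytest.approx((4 + 5) / 2)
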