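"""Content statistics: filtering, tallies, uniqueness, OLS regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdnakit.content import (
    filter_high_confidence,
    lineage_unique_means,
    regress_counts_vs_size,
    shared_identical_sequences,
    tally_counts,
    unique_fraction,
)
from tdnakit.io_formats import GeneLocus, TRNAGeneRecord
from tdnakit.synthetic import synthesize_cohort


def rec(i, isotype="Ala", anticodon="AGC", score=100.0, note="", seq=None,
        strand="+"):
    s = i * 1000
    seq = seq if seq is not None else "ACGT" * 18
    return TRNAGeneRecord(f"g{i}", GeneLocus("c", s, s + len(seq), strand),
                          isotype, anticodon, score=score, note=note,
                          gene_sequence=seq)


class TestFilter:
    def test_cutoff_is_inclusive(self):
        records = [rec(1, score=94.5), rec(2, score=95.0),
                   rec(3, score=96.1)]
        kept = filter_high_confidence(records, 95.0)
        assert [r.gene_id for r in kept] == ["g2", "g3"]

    def test_pseudo_flag_dropped(self):
        records = [rec(1, note="pseudo"), rec(2, note="possible pseudogene")]
        assert filter_high_confidence(records, 0) == []
        assert len(filter_high_confidence(records, 0,
                                          drop_pseudo=False)) == 2

    def test_minus_infinity_cutoff_is_identity(self):
        records = [rec(1, score=-10), rec(2, score=50)]
        assert filter_high_confidence(records, float("-inf"),
                                      drop_pseudo=False) == records


class TestTally:
    def test_isotype_aggregates_isoacceptors(self):
        per = {"g": [rec(1, "Ala", "AGC"), rec(2, "Ala", "AGC"),
                     rec(3, "Ala", "AGC"), rec(4, "Pro", "TGG"),
                     rec(5, "Pro", "TGG")]}
        cm = tally_counts(per)
        assert cm.isotype.loc["g", "Ala"] == 3
        assert cm.isotype.loc["g", "Pro"] == 2
        assert cm.isoacceptor.loc["g", "Ala-AGC"] == 3
        assert (cm.isotype.sum(axis=1) == cm.isoacceptor.sum(axis=1)).all()

    def test_missing_isotype_flagged_against_cohort(self):
        per = {"has_gly": [rec(1, "Gly", "GCC"), rec(2, "Ala", "AGC")],
               "no_gly": [rec(3, "Ala", "AGC")]}
        cm = tally_counts(per)
        assert "Gly" in cm.missing["no_gly"]["isotypes"]
        assert "Gly-GCC" in cm.missing["no_gly"]["isoacceptors"]
        assert "Gly" not in cm.missing["has_gly"]["isotypes"]

    def test_empty_genome_gets_zero_row(self):
        cm = tally_counts({"a": [rec(1)], "b": []})
        assert cm.isoacceptor.loc["b"].sum() == 0

    def test_order_invariance(self):
        records = [rec(1, "Ala"), rec(2, "Pro", "TGG"), rec(3, "Ser", "AGA")]
        a = tally_counts({"g": records}).isoacceptor
        b = tally_counts({"g": list(reversed(records))}).isoacceptor
        pd.testing.assert_frame_equal(a, b)


class TestUniqueness:
    def test_four_distinct_of_ten_is_forty_percent(self):
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"] + ["AAAA"] * 6
        records = [rec(i, seq=s) for i, s in enumerate(seqs)]
        pct, distinct = unique_fraction(records)
        assert pct == pytest.approx(40.0)
        assert distinct == 4

    def test_all_identical(self):
        records = [rec(i, seq="ACGTACGT") for i in range(5)]
        pct, distinct = unique_fraction(records)
        assert pct == pytest.approx(100.0 / 5)
        assert distinct == 1

    def test_empty_genome_undefined(self):
        assert unique_fraction([]) == (None, 0)

    def test_duplicating_every_gene_halves_the_percentage(self):
        seqs = ["AAAA", "CCCC", "GGGG"]
        records = [rec(i, seq=s) for i, s in enumerate(seqs)]
        doubled = records + [rec(i + 10, seq=s)
                             for i, s in enumerate(seqs)]
        pct1, d1 = unique_fraction(records)
        pct2, d2 = unique_fraction(doubled)
        assert d1 == d2
        assert pct2 == pytest.approx(pct1 / 2)

    def test_planted_duplicates_match_manifest(self, records, manifest):
        pct, _ = unique_fraction(records)
        assert pct == pytest.approx(manifest.unique_fraction_pct)

    def test_lineage_means(self):
        per = {"a": [rec(1, seq="AAAA"), rec(2, seq="AAAA")],
               "b": [rec(3, seq="CCCC")]}
        means = lineage_unique_means(per, {"a": "eudicot", "b": "monocot"})
        assert means["eudicot"] == pytest.approx(50.0)
        assert means["monocot"] == pytest.approx(100.0)


class TestSharedSequences:
    def test_sequence_in_all_three_genomes(self):
        shared_seq = "ACGT" * 18
        per = {f"g{k}": [rec(k, seq=shared_seq),
                         rec(k + 10, seq=f"{'ACGT' * 17}AAA{k}")]
               for k in range(3)}
        table = shared_identical_sequences(per)
        assert len(table) == 1
        assert table.iloc[0]["n_genomes"] == 3

    def test_no_shared_sequences_is_empty(self):
        per = {"a": [rec(1, seq="AAAA")], "b": [rec(2, seq="CCCC")]}
        assert shared_identical_sequences(per).empty

    def test_minus_strand_copy_still_matches(self):
        per = {"a": [rec(1, seq="AACCGGTT")],
               "b": [rec(2, seq="AACCGGTT", strand="-")]}
        table = shared_identical_sequences(per)
        assert len(table) == 1

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            shared_identical_sequences({"a": [rec(1)]})


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.arange(1, 11, dtype=float)
        table = pd.DataFrame({"size_mb": x, "count": 2 * x + 5})
        fit = regress_counts_vs_size(table, grouping=None)["overall"]
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        table = pd.DataFrame({"size_mb": [1.0, 2.0, 3.0, 4.0],
                              "count": [7, 7, 7, 7]})
        fit = regress_counts_vs_size(table, grouping=None)["overall"]
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_three_points(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([3.0, 5.0, 6.0])
        table = pd.DataFrame({"size_mb": x, "count": y})
        fit = regress_counts_vs_size(table, grouping=None)["overall"]
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_zero_size_variance_rejected(self):
        table = pd.DataFrame({"size_mb": [1.0, 1.0, 1.0],
                              "count": [5, 6, 7]})
        with pytest.raises(ValueError, match="variance"):
            regress_counts_vs_size(table, grouping=None)

    def test_small_groups_skipped(self):
        table = pd.DataFrame({
            "size_mb": [1.0, 2.0, 3.0, 4.0, 5.0],
            "count": [10, 20, 30, 40, 50],
            "lineage": ["a", "a", "a", "a", "b"]})
        fits = regress_counts_vs_size(table)
        assert "a" in fits and "b" not in fits

    def test_cohort_slope_in_its_confidence_interval(self):
        cohort = synthesize_cohort(n_genomes=200, slope=300, intercept=20,
                                   noise_sd=30, seed=77)
        table = pd.DataFrame({
            "size_mb": [g.size_mb for g in cohort.genomes],
            "count": [cohort.counts[g.genome_id] for g in cohort.genomes]})
        fit = regress_counts_vs_size(table, grouping=None)["overall"]
        lo, hi = fit.slope_ci(0.99)
        assert lo <= 300 <= hi

    def test_zero_slope_cohort_within_three_stderr(self):
        cohort = synthesize_cohort(n_genomes=100, slope=0, intercept=80,
                                   noise_sd=10, seed=13)
        table = pd.DataFrame({
            "size_mb": [g.size_mb for g in cohort.genomes],
            "count": [cohort.counts[g.genome_id] for g in cohort.genomes]})
        fit = regress_counts_vs_size(table, grouping=None)["overall"]
        assert abs(fit.slope) <= 3 * fit.slope_stderr
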