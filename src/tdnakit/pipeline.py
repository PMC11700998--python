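"""Orchestration of the per-genome profile and cross-genome comparison.

``run_genome_profile`` chains filter -> tally -> uniqueness -> clusters ->
flank motifs -> introns -> (optional) structure for one genome and bundles
the results; ``run_cohort_comparison`` adds per-lineage regressions,
uniqueness means, the shared-identical-sequence table, and survey-shaped
motif aggregates across genomes.  Both work on in-memory objects; when an
output directory is given every stage also writes its TSV/JSON artifact plus
a MANIFEST recording inputs, parameters, and completion state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .io_formats import (
    GenomeRecord,
    TRNAGeneRecord,
    import_annotations,
    read_genome,
    read_trnascan_table,
    read_trnascan_ss,
    write_fasta,
)
from .content import (
    filter_high_confidence,
    lineage_unique_means,
    regress_counts_vs_size,
    shared_identical_sequences,
    tally_counts,
    unique_fraction,
)
from .clusters import call_clusters, cluster_summary, clusters_to_bed
from .flanks import (
    DEFAULT_TATA_MOTIFS,
    aggregate_flank_reports,
    build_flank_report,
    extract_flanks,
    reports_to_frame,
)
from .introns import extract_introns, intron_summary, introns_to_fasta
from .structure import (
    NonCanonicalStructureError,
    extract_boxes,
    partition_cloverleaf,
)
from .synthetic import TruthManifest

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained with a MANIFEST note."""


@dataclass
class RunConfig:
    """Thresholds and inputs for a profile run (defaults are the survey's)."""

    genome_path: Optional[str] = None
    annotation_path: Optional[str] = None
    annotation_format: str = "trnascan"   # trnascan | bed6 | gff3
    ss_path: Optional[str] = None
    out_dir: Optional[str] = None
    genome_id: Optional[str] = None
    lineage: str = "other"
    windows: tuple = (50, 300, 50)
    gap_bp: int = 1000
    min_cluster_size: int = 3
    min_t_run: int = 4
    score_cutoff: float = 95.0
    drop_pseudo: bool = True
    tata_motifs: tuple = DEFAULT_TATA_MOTIFS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_bp < 0 or self.min_cluster_size < 1 \
                or self.min_t_run < 1:
            raise ValueError("thresholds must be positive")


@dataclass
class ProfileResult:
    genome_id: str
    records: list                 # high-confidence records
    n_raw: int
    flank_reports: list
    clusters: list
    introns: list
    unique_pct: Optional[float]
    distinct_count: int
    summary: dict
    structure: Optional[dict] = None


def load_annotations(path: str, fmt: str = "trnascan"
                     ) -> list[TRNAGeneRecord]:
    fmt = fmt.lower()
    if fmt == "trnascan":
        return read_trnascan_table(path)
    if fmt in ("bed6", "bed"):
        return import_annotations(path, "BED6")
    if fmt == "gff3":
        return import_annotations(path, "GFF3")
    raise ValueError(f"unknown annotation format {fmt!r}")


def run_genome_profile(config: RunConfig,
                       genome: Optional[GenomeRecord] = None,
                       records: Optional[Sequence[TRNAGeneRecord]] = None
                       ) -> ProfileResult:
    """Run every per-genome stage; pass objects directly or paths in config."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "inputs": {"genome": config.genome_path,
                   "annotation": config.annotation_path,
                   "ss": config.ss_path},
        "parameters": {
            "windows": list(config.windows), "gap_bp": config.gap_bp,
            "min_cluster_size": config.min_cluster_size,
            "min_t_run": config.min_t_run,
            "score_cutoff": config.score_cutoff,
            "tata_motifs": list(config.tata_motifs),
            "seed": config.seed},
        "version": __version__,
        "stages": {},
    }

    def stage(name: str):
        def mark(ok: bool) -> None:
            manifest["stages"][name] = "done" if ok else "failed"
            if out_dir:
                _dump_json(out_dir / "MANIFEST.json", manifest)
        return mark

    try:
        mark = stage("load")
        if genome is None:
            if config.genome_path is None:
                raise PipelineError("no genome provided")
            if not Path(config.genome_path).exists():
                raise PipelineError(
                    f"genome file not found: {config.genome_path}")
            genome = read_genome(config.genome_path,
                                 genome_id=config.genome_id,
                                 lineage=config.lineage)
        if records is None:
            if config.annotation_path is None:
                raise PipelineError("no annotation provided")
            if not Path(config.annotation_path).exists():
                raise PipelineError(
                    f"annotation file not found: {config.annotation_path}")
            records = load_annotations(config.annotation_path,
                                       config.annotation_format)
        records = list(records)
        n_raw = len(records)
        for rec in records:
            if not rec.gene_sequence and genome.contigs is not None:
                rec.gene_sequence = genome.fetch(rec.locus)
        mark(True)

        mark = stage("filter")
        kept = filter_high_confidence(records, config.score_cutoff,
                                      config.drop_pseudo)
        logger.info("%s: %d/%d high-confidence tDNAs", genome.genome_id,
                    len(kept), n_raw)
        mark(True)

        mark = stage("tally")
        counts = tally_counts({genome.genome_id: kept},
                              {genome.genome_id: genome.lineage})
        mark(True)

        mark = stage("uniqueness")
        unique_pct, distinct = unique_fraction(kept)
        mark(True)

        mark = stage("clusters")
        calls = call_clusters(kept, gap_bp=config.gap_bp,
                              min_size=config.min_cluster_size)
        csummary = cluster_summary(calls, len(kept))
        mark(True)

        mark = stage("flanks")
        flanksets = [extract_flanks(r, genome, config.windows)
                     for r in kept]
        reports = [build_flank_report(fs, config.tata_motifs,
                                      config.min_t_run)
                   for fs in flanksets]
        aggregate = aggregate_flank_reports(reports)
        mark(True)

        mark = stage("introns")
        intron_records = extract_introns(kept, genome)
        isummary = intron_summary(
            intron_records,
            lineages={genome.genome_id: genome.lineage},
            genome_of={r.gene_id: genome.genome_id
                       for r in intron_records})
        mark(True)

        structure_out = None
        if config.ss_path:
            mark = stage("structure")
            structure_out = _structure_stage(config.ss_path)
            mark(True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(str(exc)) from exc

    summary = {
        "genome_id": genome.genome_id,
        "lineage": genome.lineage,
        "size_bp": genome.size_bp,
        "n_raw": n_raw,
        "n_high_confidence": len(kept),
        "unique_pct": unique_pct,
        "distinct_count": distinct,
        "clusters": csummary,
        "flank_aggregate": aggregate,
        "n_introns": len(intron_records),
    }

    if out_dir:
        counts.isoacceptor.to_csv(out_dir / "counts_isoacceptor.tsv",
                                  sep="\t")
        counts.isotype.to_csv(out_dir / "counts_isotype.tsv", sep="\t")
        _dump_json(out_dir / "missing_isoacceptors.json", counts.missing)
        (out_dir / "clusters.tsv").write_text(clusters_to_bed(calls))
        _dump_json(out_dir / "clusters_summary.json", csummary)
        reports_to_frame(reports).to_csv(out_dir / "flank_reports.tsv",
                                         sep="\t", index=False)
        _dump_json(out_dir / "flank_aggregate.json", aggregate)
        write_fasta(out_dir / "introns.fasta",
                    introns_to_fasta(intron_records))
        isummary["per_isotype"].to_csv(out_dir / "intron_summary.tsv",
                                       sep="\t", index=False)
        if structure_out is not None:
            _dump_json(out_dir / "structure.json", structure_out)
        _dump_json(out_dir / "summary.json", summary)
        _dump_json(out_dir / "MANIFEST.json", manifest)

    return ProfileResult(
        genome_id=genome.genome_id, records=kept, n_raw=n_raw,
        flank_reports=reports, clusters=calls, introns=intron_records,
        unique_pct=unique_pct, distinct_count=distinct, summary=summary,
        structure=structure_out)


def _structure_stage(ss_path: str) -> dict:
    out = {}
    for ss in read_trnascan_ss(ss_path):
        try:
            part = partition_cloverleaf(ss)
            boxes = extract_boxes(ss.sequence, part)
            out[ss.gene_id] = {
                "element_lengths": part.element_lengths,
                "a_box": boxes.a_box, "b_box": boxes.b_box,
                "a_box_ok": boxes.a_box_ok, "b_box_ok": boxes.b_box_ok,
            }
        except NonCanonicalStructureError as exc:
            out[ss.gene_id] = {"error": str(exc)}
    return out


def run_cohort_comparison(
        genomes: Sequence[GenomeRecord],
        records_per_genome: dict,
        config: Optional[RunConfig] = None,
        counts: Optional[dict] = None,
        out_dir: Optional[str] = None) -> dict:
    """Cross-genome report: regressions, uniqueness means, shared sequences.

    ``records_per_genome`` maps genome_id to annotation records (may be
    empty for metadata-only genomes if ``counts`` supplies gene counts).
    Regressions for groups with fewer than 3 genomes are skipped with a
    warning; other outputs are still produced.
    """
    if len(genomes) < 2:
        raise ValueError("cohort comparison needs at least 2 genomes")
    config = config or RunConfig()
    lineages = {g.genome_id: g.lineage for g in genomes}

    table = pd.DataFrame({
        "genome_id": [g.genome_id for g in genomes],
        "size_mb": [g.size_mb for g in genomes],
        "lineage": [g.lineage for g in genomes],
        "count": [
            (counts or {}).get(
                g.genome_id,
                len(records_per_genome.get(g.genome_id, [])))
            for g in genomes],
    })
    fits = regress_counts_vs_size(table, grouping="lineage")

    with_records = {gid: recs for gid, recs in records_per_genome.items()
                    if recs}
    unique_means = lineage_unique_means(with_records, lineages) \
        if with_records else {}
    shared = shared_identical_sequences(with_records) \
        if len(with_records) >= 2 else pd.DataFrame()

    flank_agg = {}
    genome_by_id = {g.genome_id: g for g in genomes}
    all_reports = []
    for gid, recs in with_records.items():
        genome = genome_by_id[gid]
        if genome.contigs is None:
            continue
        for rec in recs:
            fs = extract_flanks(rec, genome, config.windows)
            all_reports.append(build_flank_report(
                fs, config.tata_motifs, config.min_t_run))
    if all_reports:
        flank_agg = aggregate_flank_reports(all_reports)

    report = {
        "n_genomes": len(genomes),
        "regressions": {k: asdict(v) for k, v in fits.items()},
        "unique_means_by_lineage": unique_means,
        "n_shared_sequences": int(len(shared)),
        "flank_aggregate": flank_agg,
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_counts.tsv", sep="\t", index=False)
        if len(shared):
            shared.to_csv(out / "shared_sequences.tsv", sep="\t",
                          index=False)
        _dump_json(out / "cohort_report.json", report)
    report["shared_sequences"] = shared
    return report


def compare_with_truth(result: ProfileResult,
                       manifest: TruthManifest) -> dict:
    """Check a profile run against a synthetic genome's planted truth.

    Returns per-aspect booleans: cluster calls (boundaries and ordered
    member lists), per-gene TATA/CAA counts, poly(T) runs, intron sequences,
    and the unique-sequence percentage.
    """
    called = sorted(
        ((c.contig, c.start, c.end, tuple(c.member_ids), c.pattern)
         for c in result.clusters))
    expected = sorted(
        ((c["contig"], c["start"], c["end"], tuple(c["members"]),
          c["pattern"]) for c in manifest.clusters))
    clusters_ok = called == expected

    truth = {g.gene_id: g for g in manifest.genes}
    reports = {r.gene_id: r for r in result.flank_reports}
    motifs_ok = polyt_ok = True
    for gid, g in truth.items():
        r = reports.get(gid)
        if r is None:
            motifs_ok = polyt_ok = False
            break
        if (r.tata_count, r.caa_count_50, r.caa_count_10) != \
                (g.tata_count, g.caa_50, g.caa_10):
            motifs_ok = False
        if [(p.offset, p.length) for p in r.polyt_runs] != \
                [tuple(t) for t in g.t_runs]:
            polyt_ok = False

    found_introns = {i.gene_id: i.sequence for i in result.introns}
    expected_introns = {g.gene_id: g.intron_sequence
                        for g in manifest.genes if g.intron_sequence}
    introns_ok = found_introns == expected_introns

    unique_ok = (result.unique_pct is None
                 and manifest.unique_fraction_pct is None) or (
        result.unique_pct is not None
        and manifest.unique_fraction_pct is not None
        and abs(result.unique_pct - manifest.unique_fraction_pct) < 1e-9)

    return {"clusters_ok": clusters_ok, "motifs_ok": motifs_ok,
            "polyt_ok": polyt_ok, "introns_ok": introns_ok,
            "unique_ok": unique_ok,
            "all_ok": clusters_ok and motifs_ok and polyt_ok
            and introns_ok and unique_ok}


def _dump_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
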