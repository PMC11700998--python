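"""Strand-aware flank extraction and regulatory-element scans.

Windows of 50 and 300 nt upstream and 50 nt downstream of each tDNA are read
5'->3' on the gene's sense strand.  Scans cover the RNA polymerase III
regulatory elements reported around plant tDNAs: upstream TATA-box motifs
(configurable motif list, default the literal 4-mer), the upstream CAA
triplet (over the full 50-nt window and the 10 bases adjacent to the gene
start), and downstream poly(T) terminator runs of at least 4 Ts, where the
first qualifying run is the terminator and any later one a backup signal.
Overlapping motif occurrences count separately (distinct start positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeRecord, TRNAGeneRecord, revcomp

DEFAULT_TATA_MOTIFS = ("TATA",)

#: extended TATA-box variants occasionally matched by plant promoter scans;
#: opt in via ``motifs=EXTENDED_TATA_MOTIFS``
EXTENDED_TATA_MOTIFS = ("TATA", "TATAA", "TATTA", "ATATA")


@dataclass
class PolyTRun:
    offset: int          # 0-based offset into the downstream window
    length: int
    role: str            # "terminator" | "backup"
    truncated: bool = False  # run touches the window edge


@dataclass
class FlankSet:
    """Per-gene sense-strand flank windows (possibly truncated at edges)."""

    gene_id: str
    upstream50: str
    upstream300: str
    downstream50: str
    truncated: bool = False


@dataclass
class FlankReport:
    gene_id: str
    tata_count: int
    tata_category: str            # "0" | "1" | "2" | ">2"
    caa_count_50: int
    caa_count_10: int
    polyt_runs: list = field(default_factory=list)  # PolyTRun

    @property
    def has_terminator(self) -> bool:
        return bool(self.polyt_runs)

    @property
    def has_backup(self) -> bool:
        return len(self.polyt_runs) > 1

    @property
    def terminator_length(self) -> Optional[int]:
        return self.polyt_runs[0].length if self.polyt_runs else None


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_flanks(record: TRNAGeneRecord, genome: GenomeRecord,
                   windows: tuple[int, int, int] = (50, 300, 50)) -> FlankSet:
    """Extract sense-strand upstream/downstream windows around one gene.

    For a plus-strand gene, upstream is the top strand immediately left of
    the start and downstream immediately right of the end; minus-strand
    genes mirror this through reverse complementation.  Windows shorter than
    nominal at contig edges are returned truncated and flagged.
    """
    w_up, w_up_long, w_down = windows
    if genome.contigs is None or record.locus.contig not in genome.contigs:
        raise ValueError(
            f"{record.gene_id}: contig {record.locus.contig!r} not in genome")
    contig = genome.contigs[record.locus.contig]
    s, e = record.locus.start, record.locus.end
    if e > len(contig):
        raise ValueError(f"{record.gene_id}: locus outside contig")

    def top(a: int, b: int) -> str:
        return contig[max(a, 0): min(b, len(contig))]

    if record.locus.strand == "+":
        up50, up300 = top(s - w_up, s), top(s - w_up_long, s)
        down50 = top(e, e + w_down)
    else:
        up50 = revcomp(top(e, e + w_up))
        up300 = revcomp(top(e, e + w_up_long))
        down50 = revcomp(top(s - w_down, s))
    truncated = (len(up50) < w_up or len(up300) < w_up_long
                 or len(down50) < w_down)
    return FlankSet(gene_id=record.gene_id, upstream50=up50,
                    upstream300=up300, downstream50=down50,
                    truncated=truncated)


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def scan_tata(window: str,
              motifs: Sequence[str] = DEFAULT_TATA_MOTIFS
              ) -> tuple[int, str]:
    """Count TATA-type motif occurrences and bin them (0 / 1 / 2 / >2).

    Counts distinct start positions where at least one motif of the set
    matches; overlapping occurrences count separately.
    """
    if not motifs:
        raise ValueError("motif set must be nonempty")
    count = 0
    for p in range(len(window)):
        if any(window.startswith(m, p) for m in motifs):
            count += 1
    if count > 2:
        category = ">2"
    else:
        category = str(count)
    return count, category


def scan_caa(flankset: FlankSet) -> tuple[int, int]:
    """CAA occurrences in the -50..-1 window and in the -10..-1 sub-window."""
    up = flankset.upstream50
    count50 = sum(1 for p in range(len(up)) if up.startswith("CAA", p))
    tail = up[-10:]
    count10 = sum(1 for p in range(len(tail)) if tail.startswith("CAA", p))
    return count50, count10


def scan_polyt(flankset: FlankSet, min_run: int = 4) -> list[PolyTRun]:
    """Maximal downstream T-runs of length >= min_run, 5'->3'.

    The first run is the terminator, later ones backups.  A run ending at
    the window edge may be truncated by it and is flagged.
    """
    window = flankset.downstream50
    runs: list[PolyTRun] = []
    i, n = 0, len(window)
    while i < n:
        if window[i] == "T":
            j = i
            while j < n and window[j] == "T":
                j += 1
            if j - i >= min_run:
                runs.append(PolyTRun(
                    offset=i, length=j - i,
                    role="terminator" if not runs else "backup",
                    truncated=(j == n)))
            i = j
        else:
            i += 1
    return runs


def build_flank_report(flankset: FlankSet,
                       motifs: Sequence[str] = DEFAULT_TATA_MOTIFS,
                       min_run: int = 4) -> FlankReport:
    """Run all scans on one gene's flanks."""
    tata_count, category = scan_tata(flankset.upstream50, motifs)
    caa50, caa10 = scan_caa(flankset)
    runs = scan_polyt(flankset, min_run=min_run)
    return FlankReport(gene_id=flankset.gene_id, tata_count=tata_count,
                       tata_category=category, caa_count_50=caa50,
                       caa_count_10=caa10, polyt_runs=runs)


# ---------------------------------------------------------------------------
# Positional composition
# ---------------------------------------------------------------------------

def composition_profile(flanksets: Sequence[FlankSet],
                        window: str = "upstream50") -> dict:
    """Positional base-frequency matrix over one window class.

    Returns the 4xL frequency matrix (rows A/C/G/T), the per-position A+T
    fraction, and per-column information content ``2 - H`` in bits (no
    small-sample correction).  Truncated windows are excluded.
    """
    usable = [getattr(f, window) for f in flanksets if not f.truncated]
    if not usable:
        raise ValueError("all windows truncated; no composition to profile")
    length = len(usable[0])
    counts = np.zeros((4, length), dtype=float)
    index = {b: k for k, b in enumerate("ACGT")}
    for seq in usable:
        for p, b in enumerate(seq):
            if b in index:
                counts[index[b], p] += 1
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(freqs), 0.0)
    ic = 2.0 + (freqs * logs).sum(axis=0)
    matrix = pd.DataFrame(freqs, index=list("ACGT"),
                          columns=range(-length, 0))
    return {
        "matrix": matrix,
        "at_fraction": freqs[0] + freqs[3],
        "information_bits": ic,
        "n_windows": len(usable),
    }


def genome_at_baseline(genome: GenomeRecord) -> float:
    """Genome-wide A+T fraction, the null against which flanks are compared."""
    if genome.contigs is None:
        raise ValueError("genome carries no sequence")
    at = total = 0
    for seq in genome.contigs.values():
        at += seq.count("A") + seq.count("T")
        total += len(seq)
    return at / total if total else float("nan")


# ---------------------------------------------------------------------------
# Aggregates (survey-table shaped summaries)
# ---------------------------------------------------------------------------

def aggregate_flank_reports(reports: Sequence[FlankReport]) -> dict:
    """Cohort-level motif prevalence in the shape of the survey tables.

    Reports the share of tDNAs with exactly 1, 2, or >2 upstream TATA
    motifs and with at least one, CAA prevalence in both upstream windows,
    and poly(T) terminator/backup prevalence with terminator length
    statistics (mean over the first run of genes that have one; the length
    range covers all qualifying runs).
    """
    n = len(reports)
    if n == 0:
        return {"n_tdnas": 0}
    tata_bins = {"1": 0, "2": 0, ">2": 0}
    for r in reports:
        if r.tata_category in tata_bins:
            tata_bins[r.tata_category] += 1
    term_lengths = [r.terminator_length for r in reports if r.has_terminator]
    all_run_lengths = [run.length for r in reports for run in r.polyt_runs]
    return {
        "n_tdnas": n,
        "pct_tata_eq1": 100.0 * tata_bins["1"] / n,
        "pct_tata_eq2": 100.0 * tata_bins["2"] / n,
        "pct_tata_gt2": 100.0 * tata_bins[">2"] / n,
        "pct_tata_ge1": 100.0 * sum(tata_bins.values()) / n,
        "pct_caa_50": 100.0 * sum(r.caa_count_50 > 0 for r in reports) / n,
        "pct_caa_10": 100.0 * sum(r.caa_count_10 > 0 for r in reports) / n,
        "pct_polyt": 100.0 * sum(r.has_terminator for r in reports) / n,
        "pct_backup_polyt": 100.0 * sum(r.has_backup for r in reports) / n,
        "mean_terminator_len": (float(np.mean(term_lengths))
                                if term_lengths else None),
        "min_run_len": min(all_run_lengths) if all_run_lengths else None,
        "max_run_len": max(all_run_lengths) if all_run_lengths else None,
    }


def reports_to_frame(reports: Sequence[FlankReport]) -> pd.DataFrame:
    """Per-gene TSV-ready table of flank findings."""
    rows = []
    for r in reports:
        rows.append({
            "gene_id": r.gene_id,
            "tata_count": r.tata_count,
            "tata_category": r.tata_category,
            "caa_count_50": r.caa_count_50,
            "caa_count_10": r.caa_count_10,
            "polyt_runs": ";".join(f"{p.offset}:{p.length}"
                                   for p in r.polyt_runs),
            "has_terminator": r.has_terminator,
            "has_backup": r.has_backup,
        })
    return pd.DataFrame(rows)
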