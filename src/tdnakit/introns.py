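"""Intron extraction from annotated tDNAs and catalog/conservation summaries.

Plant nuclear pre-tRNA introns sit at the canonical position in the
anticodon loop; beyond the ubiquitous eMet and Tyr carriers they appear
sporadically in other isotypes, so the summary keeps a separate catalog of
non-Met/non-Tyr carriers and flags unusually long introns (the observed
background is ~10-20 bp with rare outliers far above).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneLocus, GenomeRecord, TRNAGeneRecord


@dataclass
class IntronRecord:
    gene_id: str
    isotype: str
    anticodon: str
    sequence: str        # sense strand
    length: int
    locus: GeneLocus

    def __post_init__(self) -> None:
        if not (self.length == len(self.locus) == len(self.sequence) >= 1):
            raise ValueError(
                f"{self.gene_id}: inconsistent intron length/locus/sequence")


#: isotypes whose introns are ubiquitous (everything else goes in the
#: rare-carrier catalog)
CANONICAL_INTRON_ISOTYPES = {"eMet", "Met", "iMet", "Tyr"}


def extract_introns(records: Sequence[TRNAGeneRecord],
                    genome: Optional[GenomeRecord] = None
                    ) -> list[IntronRecord]:
    """Pull sense-strand intron sequences out of intron-bearing genes.

    Sequences come from the genome when one is attached, else from the
    record's own gene_sequence.  Genes without introns are skipped; an
    intron locus outside its gene locus is an error (enforced at record
    construction, re-checked here).
    """
    out: list[IntronRecord] = []
    for rec in records:
        if rec.intron is None:
            continue
        if not rec.locus.contains(rec.intron):
            raise ValueError(
                f"{rec.gene_id}: intron locus outside gene locus")
        if genome is not None and genome.contigs is not None:
            seq = genome.fetch(rec.intron)
        else:
            seq = rec.intron_sequence()
        out.append(IntronRecord(
            gene_id=rec.gene_id, isotype=rec.isotype,
            anticodon=rec.anticodon, sequence=seq,
            length=len(rec.intron), locus=rec.intron))
    return out


def intron_summary(introns: Sequence[IntronRecord],
                   lineages: Optional[Mapping[str, str]] = None,
                   genome_of: Optional[Mapping[str, str]] = None,
                   outlier_bp: int = 50) -> dict:
    """Length statistics per isotype (and lineage) plus rare-carrier catalog.

    ``genome_of`` maps gene_id -> genome_id (single-genome inputs may omit
    it); ``lineages`` maps genome_id -> lineage label.  Introns longer than
    ``outlier_bp`` are flagged as length outliers.
    """
    lineages = dict(lineages or {})
    genome_of = dict(genome_of or {})

    rows = []
    for rec in introns:
        gid = genome_of.get(rec.gene_id, "genome")
        rows.append({
            "gene_id": rec.gene_id, "genome_id": gid,
            "lineage": lineages.get(gid, "other"),
            "isotype": rec.isotype, "anticodon": rec.anticodon,
            "length": rec.length,
        })
    frame = pd.DataFrame(rows, columns=["gene_id", "genome_id", "lineage",
                                        "isotype", "anticodon", "length"])
    if frame.empty:
        stats = pd.DataFrame(columns=["isotype", "lineage", "count", "mean",
                                      "min", "max"])
    else:
        stats = (frame.groupby(["isotype", "lineage"])["length"]
                 .agg(count="size", mean="mean", min="min", max="max")
                 .reset_index())

    rare = frame[~frame["isotype"].isin(CANONICAL_INTRON_ISOTYPES)]
    if rare.empty:
        catalog = pd.DataFrame(columns=["isotype", "genome_id", "count"])
    else:
        catalog = (rare.groupby(["isotype", "genome_id"])
                   .size().rename("count").reset_index())

    outliers = frame[frame["length"] > outlier_bp]
    return {
        "per_isotype": stats,
        "rare_carriers": catalog,
        "outliers": outliers.reset_index(drop=True),
        "n_introns": len(frame),
    }


def column_conservation(alignment: Sequence[tuple[str, str]],
                        threshold: float = 0.8) -> dict:
    """Per-column conservation of an intron (or any) alignment.

    For each column the majority non-gap base and its frequency over all
    rows (gap-inclusive denominator) are reported, with information content
    ``2 - H`` in bits where the entropy is taken over non-gap bases only.
    Maximal runs of columns whose majority frequency reaches ``threshold``
    are returned as conserved motif spans with consensus strings.
    """
    if not alignment:
        raise ValueError("alignment is empty")
    length = len(alignment[0][1])
    if any(len(seq) != length for _, seq in alignment):
        raise ValueError("alignment rows have unequal lengths")
    n_rows = len(alignment)

    cols = []
    for c in range(length):
        column = [seq[c] for _, seq in alignment]
        counts = {b: column.count(b) for b in "ACGT"}
        nongap = sum(counts.values())
        base, best = max(counts.items(), key=lambda kv: kv[1])
        freq = best / n_rows
        if nongap:
            ps = np.array([v / nongap for v in counts.values() if v > 0])
            ic = 2.0 + float((ps * np.log2(ps)).sum())
        else:
            base, ic = "-", 0.0
        cols.append({"column": c, "majority_base": base,
                     "majority_freq": freq, "ic_bits": ic,
                     "nongap_rows": nongap,
                     "conserved": freq >= threshold and nongap > 0})

    spans = []
    start = None
    for c, info in enumerate(cols):
        if info["conserved"] and start is None:
            start = c
        elif not info["conserved"] and start is not None:
            spans.append(_span(cols, start, c))
            start = None
    if start is not None:
        spans.append(_span(cols, start, length))

    return {"columns": pd.DataFrame(cols), "spans": spans,
            "threshold": threshold, "n_rows": n_rows}


def _span(cols: list, start: int, end: int) -> dict:
    return {"start": start, "end": end,
            "consensus": "".join(cols[c]["majority_base"]
                                 for c in range(start, end))}


def introns_to_fasta(introns: Sequence[IntronRecord]) -> list[tuple[str, str]]:
    """FASTA-ready pairs, one per intron: ``gene_id|isotype|anticodon``."""
    return [(f"{r.gene_id}|{r.isotype}|{r.anticodon}", r.sequence)
            for r in introns]
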