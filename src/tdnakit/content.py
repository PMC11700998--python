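"""Per-genome tDNA content: filtering, tallies, uniqueness, regression.

The score filter reimplements the high-confidence cutoff applied by
tRNAscan-SE post-filtering (default bit-score threshold 95, pseudogene notes
dropped).  Uniqueness compares full genomic gene sequences - uppercase,
sense strand, introns included by default - which is the strictest
reproducible definition; set ``include_introns=False`` to compare spliced
sequences instead.  Regressions are ordinary least squares of gene count on
genome size in Mb, with the two-sided t-test p-value on the slope (the
``lm`` summary convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TRNAGeneRecord

logger = logging.getLogger(__name__)

PSEUDO_FLAG = "pseudo"


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float = float("nan")

    def slope_ci(self, level: float = 0.99) -> tuple[float, float]:
        """Confidence interval for the slope from the t distribution."""
        tcrit = stats.t.ppf(0.5 + level / 2, df=self.n - 2)
        half = tcrit * self.slope_stderr
        return self.slope - half, self.slope + half


@dataclass
class CountMatrix:
    """Genome x isoacceptor (and x isotype) count tables with lineage labels.

    The isotype table is always the isoacceptor table aggregated over
    anticodons.
    """

    isoacceptor: pd.DataFrame
    isotype: pd.DataFrame
    lineages: dict
    missing: dict      # genome_id -> {"isoacceptors": [...], "isotypes": [..]}


def filter_high_confidence(records: Sequence[TRNAGeneRecord],
                           score_cutoff: float = 95.0,
                           drop_pseudo: bool = True
                           ) -> list[TRNAGeneRecord]:
    """Keep records with score >= cutoff (and no pseudogene note)."""
    kept = []
    for rec in records:
        if rec.score < score_cutoff:
            continue
        if drop_pseudo and PSEUDO_FLAG in rec.note.lower():
            continue
        kept.append(rec)
    dropped = len(records) - len(kept)
    logger.info("high-confidence filter: kept %d, dropped %d (cutoff %.3g)",
                len(kept), dropped, score_cutoff)
    if not kept and records:
        logger.warning("high-confidence filter removed every record")
    return kept


def tally_counts(records_per_genome: Mapping[str, Sequence[TRNAGeneRecord]],
                 lineages: Optional[Mapping[str, str]] = None) -> CountMatrix:
    """Tally isotype and isoacceptor counts per genome.

    Unknown anticodons tally under ``NNN``.  The missing report lists, per
    genome, the isotype-anticodon combinations (and isotypes) observed
    somewhere in the cohort but absent from that genome - the white cells of
    a content heatmap.
    """
    lineages = dict(lineages or {})
    rows = {}
    for gid, records in records_per_genome.items():
        counts: dict[str, int] = {}
        for rec in records:
            ac = rec.anticodon if rec.anticodon else "NNN"
            counts[f"{rec.isotype}-{ac}"] = counts.get(
                f"{rec.isotype}-{ac}", 0) + 1
        rows[gid] = counts
    isoacceptor = pd.DataFrame.from_dict(rows, orient="index")
    isoacceptor = isoacceptor.reindex(index=list(records_per_genome),
                                      columns=sorted(isoacceptor.columns))
    isoacceptor = isoacceptor.fillna(0).astype(int)

    iso_cols = [c.rsplit("-", 1)[0] for c in isoacceptor.columns]
    isotype = isoacceptor.T.groupby(iso_cols).sum().T

    missing = {}
    for gid in isoacceptor.index:
        missing[gid] = {
            "isoacceptors": [c for c in isoacceptor.columns
                             if isoacceptor.loc[gid, c] == 0],
            "isotypes": [c for c in isotype.columns
                         if isotype.loc[gid, c] == 0],
        }
    return CountMatrix(isoacceptor=isoacceptor, isotype=isotype,
                       lineages={g: lineages.get(g, "other")
                                 for g in isoacceptor.index},
                       missing=missing)


def unique_fraction(records: Sequence[TRNAGeneRecord],
                    include_introns: bool = True
                    ) -> tuple[Optional[float], int]:
    """Percentage of distinct gene sequences and the distinct count.

    Sequences are compared uppercase on the sense strand, introns included
    unless ``include_introns`` is False.  Returns ``(None, 0)`` for an empty
    genome (the fraction is undefined).
    """
    if not records:
        return None, 0
    seqs = set()
    for rec in records:
        seq = (rec.gene_sequence if include_introns
               else rec.mature_sequence())
        seqs.add(seq.upper())
    distinct = len(seqs)
    return 100.0 * distinct / len(records), distinct


def lineage_unique_means(records_per_genome: Mapping[str, Sequence[
        TRNAGeneRecord]], lineages: Mapping[str, str],
        include_introns: bool = True) -> dict:
    """Mean unique-sequence percentage per lineage across genomes."""
    per_lineage: dict[str, list[float]] = {}
    for gid, records in records_per_genome.items():
        pct, _ = unique_fraction(records, include_introns=include_introns)
        if pct is None:
            continue
        per_lineage.setdefault(lineages.get(gid, "other"), []).append(pct)
    return {lab: float(np.mean(v)) for lab, v in per_lineage.items()}


def shared_identical_sequences(
        records_per_genome: Mapping[str, Sequence[TRNAGeneRecord]],
        min_genomes: int = 2) -> pd.DataFrame:
    """Exact-identity search for gene sequences shared across genomes.

    Compares full sense-strand gene sequences (a minus-strand copy matches a
    plus-strand copy of the same gene).  Returns one row per sequence found
    in at least ``min_genomes`` genomes with its isoacceptor and carriers.
    """
    if len(records_per_genome) < 2:
        raise ValueError("cross-genome search needs at least 2 genomes")
    carriers: dict[str, dict] = {}
    for gid, records in records_per_genome.items():
        for rec in records:
            seq = rec.gene_sequence.upper()
            entry = carriers.setdefault(
                seq, {"isoacceptor": rec.isoacceptor, "genomes": set()})
            entry["genomes"].add(gid)
    rows = []
    for seq, entry in carriers.items():
        if len(entry["genomes"]) >= min_genomes:
            rows.append({
                "sequence": seq,
                "isoacceptor": entry["isoacceptor"],
                "n_genomes": len(entry["genomes"]),
                "genomes": ",".join(sorted(entry["genomes"])),
            })
    frame = pd.DataFrame(rows, columns=["sequence", "isoacceptor",
                                        "n_genomes", "genomes"])
    return frame.sort_values(["n_genomes", "sequence"],
                             ascending=[False, True]).reset_index(drop=True)


def regress_counts_vs_size(table: pd.DataFrame,
                           grouping: Optional[str] = "lineage"
                           ) -> dict[str, RegressionFit]:
    """OLS of gene count on genome size (Mb), overall and per group.

    ``table`` needs columns ``size_mb`` and ``count`` (plus the grouping
    column).  Groups with fewer than 3 genomes are skipped with a warning;
    zero variance in size is an error (the regression is undefined).
    """
    fits: dict[str, RegressionFit] = {}

    def fit_one(sub: pd.DataFrame, label: str) -> None:
        if len(sub) < 3:
            logger.warning("group %r has n=%d < 3; regression skipped",
                           label, len(sub))
            return
        x = sub["size_mb"].to_numpy(dtype=float)
        y = sub["count"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(
                f"group {label!r}: zero variance in genome size; "
                "regression undefined")
        if np.ptp(y) == 0:
            # constant response: flat line, no explained variance
            fits[label] = RegressionFit(
                slope=0.0, intercept=float(y[0]), r_squared=0.0,
                p_value=1.0, n=len(sub), slope_stderr=0.0)
            return
        res = stats.linregress(x, y)
        fits[label] = RegressionFit(
            slope=float(res.slope), intercept=float(res.intercept),
            r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
            n=len(sub), slope_stderr=float(res.stderr))

    fit_one(table, "overall")
    if grouping and grouping in table.columns:
        for label, sub in table.groupby(grouping):
            fit_one(sub, str(label))
    return fits
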