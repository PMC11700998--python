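"""tDNA cluster calling by the density criterion (>=3 genes within 1 kb).

Merging follows BEDTools ``merge -d`` semantics: genes sorted by start on a
contig join one cluster when the end-to-start gap between neighbours is at
most ``gap_bp`` (overlapping or bookended genes always merge); merged groups
with at least ``min_size`` members are emitted.  Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import TRNAGeneRecord


@dataclass
class ClusterCall:
    """A maximal merged run of tDNAs passing the density criterion."""

    contig: str
    start: int
    end: int
    members: list = field(default_factory=list)  # TRNAGeneRecord, by start
    pattern: str = "mixed"

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]


def call_clusters(records: Sequence[TRNAGeneRecord], gap_bp: int = 1000,
                  min_size: int = 3,
                  start_to_start: bool = False) -> list[ClusterCall]:
    """Single-linkage merge of tDNAs into clusters, per contig.

    With ``start_to_start`` the 1-kb criterion is measured between start
    coordinates instead of the end-to-start gap.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    by_contig: dict[str, list[TRNAGeneRecord]] = {}
    for rec in records:
        by_contig.setdefault(rec.locus.contig, []).append(rec)

    calls: list[ClusterCall] = []
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda r: (r.locus.start,
                                                         r.locus.end))
        group: list[TRNAGeneRecord] = []
        max_end = 0
        for rec in genes:
            if not group:
                group = [rec]
                max_end = rec.locus.end
                continue
            # gap to the running envelope end (BEDTools merge semantics);
            # start-to-start distances are monotone, so the previous start
            # suffices there
            dist = (rec.locus.start - group[-1].locus.start if start_to_start
                    else rec.locus.start - max_end)
            if dist <= gap_bp:
                group.append(rec)
                max_end = max(max_end, rec.locus.end)
            else:
                if len(group) >= min_size:
                    calls.append(_finish(contig, group))
                group = [rec]
                max_end = rec.locus.end
        if len(group) >= min_size:
            calls.append(_finish(contig, group))
    return calls


def _finish(contig: str, group: list[TRNAGeneRecord]) -> ClusterCall:
    call = ClusterCall(
        contig=contig,
        start=min(r.locus.start for r in group),
        end=max(r.locus.end for r in group),
        members=list(group))
    call.pattern = classify_cluster(call)
    return call


def classify_cluster(cluster: ClusterCall) -> str:
    """Label a cluster homogeneous, strictly alternating, or mixed.

    Classification is at isotype level: homogeneous when all members share
    one isotype; alternating when exactly two isotypes occur and no two
    adjacent members (by start order) repeat; anything else is mixed.
    """
    isotypes = [m.isotype for m in cluster.members]
    kinds = sorted(set(isotypes), key=isotypes.index)
    if len(kinds) == 1:
        return f"homogeneous:{kinds[0]}"
    if len(kinds) == 2 and all(a != b for a, b in zip(isotypes,
                                                      isotypes[1:])):
        return f"alternating:{kinds[0]}/{kinds[1]}"
    return "mixed"


def cluster_summary(clusters: Sequence[ClusterCall],
                    total_genes: int) -> dict:
    """Per-genome clustering statistics (counts, % clustered, largest)."""
    if total_genes < 0:
        raise ValueError("total_genes must be >= 0")
    clustered = sum(c.size for c in clusters)
    if total_genes == 0 and clustered > 0:
        raise ValueError("clusters reported for a genome with zero genes")
    largest = max(clusters, key=lambda c: c.size, default=None)
    return {
        "cluster_count": len(clusters),
        "clustered_genes": clustered,
        "clustered_pct": (100.0 * clustered / total_genes
                          if total_genes else 0.0),
        "largest_cluster_size": largest.size if largest else 0,
        "largest_cluster_pattern": largest.pattern if largest else "",
    }


def clusters_to_bed(clusters: Sequence[ClusterCall]) -> str:
    """BED-like TSV with a member-count and pattern column."""
    lines = []
    for c in clusters:
        lines.append(f"{c.contig}\t{c.start}\t{c.end}\t{c.size}\t{c.pattern}"
                     f"\t{','.join(c.member_ids)}")
    return "\n".join(lines) + ("\n" if lines else "")
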