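"""Readers and writers for the file formats the tDNA pipeline touches.

All genomic coordinates are normalized to a single internal convention:
0-based, half-open ``[start, end)`` intervals with an explicit ``+``/``-``
strand.  The tRNAscan-SE convention (1-based inclusive, minus strand encoded
by ``begin > end``) is confined to :func:`read_trnascan_table` and
:func:`write_trnascan_table`; BED6 shares the internal convention and GFF3 is
shifted to 1-based inclusive only at the file boundary.

Sequences are stored as uppercase DNA (``U`` mapped to ``T`` on input by
default); RNA rendering, if wanted, happens on output only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Isotype labels that are not plain 3-letter amino-acid codes.
SPECIAL_ISOTYPES = {"eMet", "iMet", "Sup", "Undet"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware via Biopython)."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneLocus:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid locus {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GeneLocus") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TRNAGeneRecord:
    """One annotated tRNA gene (tDNA)."""

    gene_id: str
    locus: GeneLocus
    isotype: str
    anticodon: str  # 3-mer over ACGT, or "NNN" when unknown
    intron: Optional[GeneLocus] = None
    score: float = 0.0
    note: str = ""
    gene_sequence: str = ""  # sense-strand nucleotides, introns included

    def __post_init__(self) -> None:
        if self.intron is not None:
            if not (
                self.locus.contig == self.intron.contig
                and self.locus.start < self.intron.start
                and self.intron.end < self.locus.end
            ):
                raise ValueError(
                    f"{self.gene_id}: intron {self.intron} does not lie "
                    f"strictly inside gene locus {self.locus}"
                )
        if self.gene_sequence and len(self.gene_sequence) != len(self.locus):
            raise ValueError(
                f"{self.gene_id}: gene_sequence length "
                f"{len(self.gene_sequence)} != locus length {len(self.locus)}"
            )
        if self.anticodon not in ("", "NNN") and len(self.anticodon) != 3:
            raise ValueError(f"{self.gene_id}: anticodon must be a 3-mer")

    @property
    def isoacceptor(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    def intron_sense_offset(self) -> Optional[int]:
        """Offset of the intron start on the gene's sense strand, or None."""
        if self.intron is None:
            return None
        if self.locus.strand == "+":
            return self.intron.start - self.locus.start
        return self.locus.end - self.intron.end

    def mature_sequence(self) -> str:
        """Gene sequence with the intron spliced out (sense strand)."""
        if self.intron is None:
            return self.gene_sequence
        off = self.intron_sense_offset()
        ilen = len(self.intron)
        return self.gene_sequence[:off] + self.gene_sequence[off + ilen:]

    def intron_sequence(self) -> str:
        """Sense-strand intron sequence (empty when intron-less)."""
        if self.intron is None:
            return ""
        off = self.intron_sense_offset()
        return self.gene_sequence[off: off + len(self.intron)]


@dataclass
class GenomeRecord:
    """Named contig sequences plus genome-level metadata.

    ``contigs`` may be ``None`` for metadata-only genomes (e.g. cohort rows
    carrying only a declared size for regression); whenever sequences are
    present, ``size_bp`` must equal their summed length.
    """

    genome_id: str
    lineage: str = "other"
    contigs: Optional[dict[str, str]] = None
    size_bp: int = 0

    def __post_init__(self) -> None:
        if self.contigs is not None:
            total = sum(len(s) for s in self.contigs.values())
            if self.size_bp == 0:
                self.size_bp = total
            elif self.size_bp != total:
                raise ValueError(
                    f"{self.genome_id}: size_bp {self.size_bp} != summed "
                    f"contig length {total}"
                )

    @property
    def size_mb(self) -> float:
        return self.size_bp / 1e6

    def fetch(self, locus: GeneLocus) -> str:
        """Sense-strand sequence at a locus (revcomp for minus strand)."""
        if self.contigs is None:
            raise ValueError(f"{self.genome_id}: no sequence attached")
        try:
            contig = self.contigs[locus.contig]
        except KeyError:
            raise KeyError(
                f"{self.genome_id}: unknown contig {locus.contig!r}"
            ) from None
        if locus.end > len(contig):
            raise ValueError(
                f"locus {locus} extends past contig end ({len(contig)} bp)"
            )
        seq = contig[locus.start: locus.end]
        return revcomp(seq) if locus.strand == "-" else seq


@dataclass
class SecondaryStructureRecord:
    """A tRNA sequence with its nested base-pairing (0-based pairs, i < j)."""

    gene_id: str
    sequence: str
    pairing: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairing:
            if not (0 <= i < j < len(self.sequence)):
                raise ValueError(f"{self.gene_id}: pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise ValueError(f"{self.gene_id}: position paired twice")
            seen.update((i, j))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike, u_to_t: bool = True) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file as ``[(identifier, sequence), ...]``.

    Sequences are uppercased; ``U`` is mapped to ``T`` unless ``u_to_t`` is
    False.  Duplicate identifiers and empty sequences are errors.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if u_to_t:
            seq = seq.replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        out.append((rec.id, seq))
    return out


def write_fasta(path: PathLike, records: Iterable[tuple[str, str]],
                width: int = 60) -> None:
    """Write ``(identifier, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_genome(path: PathLike, genome_id: Optional[str] = None,
                lineage: str = "other") -> GenomeRecord:
    """Load a genome FASTA into a :class:`GenomeRecord`."""
    contigs = dict(read_fasta(path))
    gid = genome_id or Path(path).stem
    return GenomeRecord(genome_id=gid, lineage=lineage, contigs=contigs)


# ---------------------------------------------------------------------------
# tRNAscan-SE .out tables
# ---------------------------------------------------------------------------

def _coords_to_internal(begin: int, end: int) -> tuple[int, int, str]:
    """1-based inclusive (minus strand iff begin > end) -> 0-based half-open."""
    if begin == end:
        raise FormatError(f"degenerate coordinates begin == end == {begin}")
    if begin < end:
        return begin - 1, end, "+"
    return end - 1, begin, "-"


def _coords_to_trnascan(start: int, end: int, strand: str) -> tuple[int, int]:
    """Inverse of :func:`_coords_to_internal` (an involution on rows)."""
    if strand == "+":
        return start + 1, end
    return end, start + 1


def read_trnascan_table(path: PathLike) -> list[TRNAGeneRecord]:
    """Parse a tRNAscan-SE ``.out`` table into internal records.

    The first nine columns are fixed (name, tRNA#, begin, end, isotype,
    anticodon, intron begin, intron end, score); any trailing columns (the
    plain layout's pseudogene note or the ``-H`` layout's extra score columns)
    are joined verbatim into ``note``.  Up to three leading header lines are
    tolerated.
    """
    records: list[TRNAGeneRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            fields = line.split()
        if len(fields) < 9:
            if lineno <= 3:
                continue  # header
            raise FormatError(f"{path}:{lineno}: expected >= 9 columns")
        fields = [f.strip() for f in fields]
        try:
            num = int(fields[1])
            begin, end = int(fields[2]), int(fields[3])
            ib, ie = int(fields[6]), int(fields[7])
            score = float(fields[8])
        except ValueError:
            if lineno <= 3:
                continue  # header line (e.g. "Name  tRNA #  Begin  End ...")
            raise FormatError(
                f"{path}:{lineno}: non-numeric coordinate or score field"
            ) from None
        try:
            start0, end0, strand = _coords_to_internal(begin, end)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        contig = fields[0]
        intron = None
        if not (ib == 0 and ie == 0):
            istart, iend, _ = _coords_to_internal(ib, ie)
            intron = GeneLocus(contig, istart, iend, strand)
        note = " ".join(fields[9:]).strip()
        records.append(
            TRNAGeneRecord(
                gene_id=f"{contig}.trna{num}",
                locus=GeneLocus(contig, start0, end0, strand),
                isotype=fields[4],
                anticodon=fields[5].upper().replace("U", "T"),
                intron=intron,
                score=score,
                note=note,
            )
        )
    return records


def write_trnascan_table(path: PathLike,
                         records: Sequence[TRNAGeneRecord]) -> None:
    """Write records in the tRNAscan-SE ``.out`` dialect (3 header lines)."""
    with open(path, "w") as fh:
        fh.write("Sequence\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\t\t"
                 "Inf\t\n")
        fh.write("Name    \t#\tBegin\tEnd\tType\tCodon\tBegin\tEnd\t"
                 "Score\tNote\n")
        fh.write("--------\t------\t-----\t---\t----\t-----\t-----\t----\t"
                 "-----\t----\n")
        for rec in records:
            begin, end = _coords_to_trnascan(
                rec.locus.start, rec.locus.end, rec.locus.strand)
            if rec.intron is None:
                ib = ie = 0
            else:
                ib, ie = _coords_to_trnascan(
                    rec.intron.start, rec.intron.end, rec.locus.strand)
            num = rec.gene_id.rsplit("trna", 1)[-1]
            if not num.isdigit():
                num = "1"
            fh.write(
                f"{rec.locus.contig}\t{num}\t{begin}\t{end}\t{rec.isotype}\t"
                f"{rec.anticodon}\t{ib}\t{ie}\t{rec.score:g}\t{rec.note}\n"
            )


# ---------------------------------------------------------------------------
# tRNAscan-SE .ss secondary-structure files
# ---------------------------------------------------------------------------

def pairs_from_brackets(structure: str, open_chars: str = ">(",
                        close_chars: str = "<)") -> frozenset[tuple[int, int]]:
    """Stack-match a bracket string (``>``/``<`` or dot-bracket) into pairs."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(structure):
        if ch in open_chars:
            stack.append(i)
        elif ch in close_chars:
            if not stack:
                raise FormatError(
                    f"unbalanced structure: close at position {i} with no "
                    "open partner"
                )
            pairs.add((stack.pop(), i))
    if stack:
        raise FormatError(
            f"unbalanced structure: {len(stack)} unclosed position(s)"
        )
    return frozenset(pairs)


def read_trnascan_ss(path: PathLike) -> list[SecondaryStructureRecord]:
    """Parse a tRNAscan-SE ``.ss`` file (blocks with ``Seq:``/``Str:`` lines).

    The structure alphabet is ``>``, ``<``, ``.`` with ``>`` pairing the
    matching downstream ``<``.
    """
    records: list[SecondaryStructureRecord] = []
    gene_id = ""
    seq = struct = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Seq:"):
                seq = line[4:].strip().upper().replace("U", "T")
            elif line.startswith("Str:"):
                struct = line[4:].strip()
            elif not line.startswith(("Type:", "Pre:", "Possible", "*")):
                # new block header, e.g. "chr1.trna1 (1001-1072)  Length: 72 bp"
                if seq is not None and struct is not None:
                    records.append(_finish_ss_block(gene_id, seq, struct))
                    seq = struct = None
                gene_id = line.split()[0]
    if seq is not None and struct is not None:
        records.append(_finish_ss_block(gene_id, seq, struct))
    return records


def _finish_ss_block(gene_id: str, seq: str,
                     struct: str) -> SecondaryStructureRecord:
    try:
        pairs = pairs_from_brackets(struct, open_chars=">", close_chars="<")
    except FormatError as exc:
        raise FormatError(f"gene block {gene_id!r}: {exc}") from None
    return SecondaryStructureRecord(gene_id=gene_id, sequence=seq,
                                    pairing=pairs)


def write_trnascan_ss(path: PathLike, records: Iterable[
        SecondaryStructureRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            struct = ["."] * len(rec.sequence)
            for i, j in rec.pairing:
                struct[i], struct[j] = ">", "<"
            fh.write(f"{rec.gene_id} (1-{len(rec.sequence)})\t"
                     f"Length: {len(rec.sequence)} bp\n")
            fh.write(f"Seq: {rec.sequence}\n")
            fh.write(f"Str: {''.join(struct)}\n\n")


# ---------------------------------------------------------------------------
# BED6 / GFF3 export and import
# ---------------------------------------------------------------------------

def export_annotations(path: PathLike, records: Sequence[TRNAGeneRecord],
                       fmt: str = "BED6") -> None:
    """Export records as BED6 (internal convention) or GFF3 (1-based)."""
    fmt = fmt.upper()
    if fmt == "BED6":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(
                    f"{rec.locus.contig}\t{rec.locus.start}\t{rec.locus.end}"
                    f"\t{rec.isoacceptor}\t{rec.score:g}\t{rec.locus.strand}\n"
                )
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in records:
                attrs = [f"ID={rec.gene_id}", f"isotype={rec.isotype}",
                         f"anticodon={rec.anticodon}"]
                if rec.intron is not None:
                    attrs.append(
                        f"intron={rec.intron.start + 1}..{rec.intron.end}")
                if rec.note:
                    attrs.append(f"note={rec.note}")
                fh.write(
                    f"{rec.locus.contig}\ttdnakit\ttRNA\t"
                    f"{rec.locus.start + 1}\t{rec.locus.end}\t{rec.score:g}\t"
                    f"{rec.locus.strand}\t.\t{';'.join(attrs)}\n"
                )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}; "
                         "expected BED6 or GFF3")


def import_annotations(path: PathLike, fmt: str = "BED6"
                       ) -> list[TRNAGeneRecord]:
    """Inverse of :func:`export_annotations` (BED6 drops intron/note)."""
    fmt = fmt.upper()
    records: list[TRNAGeneRecord] = []
    if fmt == "BED6":
        with open(path) as fh:
            for k, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 6:
                    raise FormatError(f"{path}:{k}: BED6 needs 6 columns")
                isotype, _, anticodon = f[3].partition("-")
                records.append(TRNAGeneRecord(
                    gene_id=f"{f[0]}.trna{k}",
                    locus=GeneLocus(f[0], int(f[1]), int(f[2]), f[5]),
                    isotype=isotype, anticodon=anticodon or "NNN",
                    score=float(f[4])))
    elif fmt == "GFF3":
        with open(path) as fh:
            for k, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    raise FormatError(f"{path}:{k}: GFF3 needs 9 columns")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if kv)
                strand = f[6]
                intron = None
                if "intron" in attrs:
                    a, b = attrs["intron"].split("..")
                    intron = GeneLocus(f[0], int(a) - 1, int(b), strand)
                records.append(TRNAGeneRecord(
                    gene_id=attrs.get("ID", f"{f[0]}.trna{k}"),
                    locus=GeneLocus(f[0], int(f[3]) - 1, int(f[4]), strand),
                    isotype=attrs.get("isotype", "Undet"),
                    anticodon=attrs.get("anticodon", "NNN"),
                    intron=intron,
                    score=float(f[5]) if f[5] != "." else 0.0,
                    note=attrs.get("note", "")))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return records


# ---------------------------------------------------------------------------
# Alignments and trees
# ---------------------------------------------------------------------------

def read_alignment(path: PathLike) -> list[tuple[str, str]]:
    """Read an aligned FASTA; rows keep gaps and must share one length."""
    rows = [(rid, seq) for rid, seq in _read_gapped_fasta(path)]
    if not rows:
        warnings.warn(f"{path}: empty alignment", stacklevel=2)
        return rows
    length = len(rows[0][1])
    ragged = [rid for rid, seq in rows if len(seq) != length]
    if ragged:
        raise FormatError(
            f"{path}: ragged alignment rows: {', '.join(ragged)}")
    return rows


def _read_gapped_fasta(path: PathLike) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper().replace("U", "T")


def read_newick(path_or_string: PathLike) -> dendropy.Tree:
    """Parse a single rooted newick tree (file path or literal string)."""
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        raise FormatError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(leaves) == 0:
        raise FormatError("newick tree has no labeled leaves")
    root_children = len(tree.seed_node.child_nodes())
    if root_children > 2:
        logger.info("newick tree has a non-binary (%d-child) root",
                    root_children)
    return tree
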