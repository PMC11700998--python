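"""Synthetic genomes with planted tDNA features and machine-readable truth.

The generator emulates the conditions a comparative tDNA survey meets in real
plant assemblies: canonical cloverleaf tRNA genes on both strands, optional
introns at the canonical position (after the 37th template base), upstream
TATA/CAA promoter motifs, downstream poly(T) terminators with optional backup
runs, tandem and alternating gene clusters, duplicated gene copies, and
cohorts with a controllable linear gene-count-vs-genome-size relationship.

Every planted feature is recorded in a :class:`TruthManifest` so downstream
stages can be verified exactly.  Expected motif counts are derived by scanning
a "skeleton" that contains only planted material; the random background of
each constrained flank window is then rejection-sampled until a naive scan of
the assembled window matches the skeleton-derived expectation, which keeps the
expected counts exact without constraining the rest of the genome.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    GeneLocus,
    GenomeRecord,
    SecondaryStructureRecord,
    TRNAGeneRecord,
    revcomp,
)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: scan windows fixed by the study design (50 nt on either side of the gene)
UPSTREAM_SCAN = 50
DOWNSTREAM_SCAN = 50

#: mature cloverleaf geometry (0-based positions on the 72-nt template)
MATURE_LEN = 72
ACCEPTOR_PAIRS = tuple((i, 70 - i) for i in range(7))
D_PAIRS = tuple((9 + k, 24 - k) for k in range(4))
ANTICODON_PAIRS = tuple((26 + k, 42 - k) for k in range(5))
T_PAIRS = tuple((47 + k, 63 - k) for k in range(5))
ALL_PAIRS = ACCEPTOR_PAIRS + D_PAIRS + ANTICODON_PAIRS + T_PAIRS
ANTICODON_POSITIONS = (33, 34, 35)  # 1-based 34-36
INTRON_INSERT_AFTER = 37            # inserted after the 37th mature base

#: a modest canonical isoacceptor table used when sampling cohort gene content
ISOACCEPTORS = [
    ("Ala", "AGC"), ("Ala", "CGC"), ("Ala", "TGC"), ("Gly", "GCC"),
    ("Gly", "TCC"), ("Pro", "TGG"), ("Pro", "AGG"), ("Ser", "AGA"),
    ("Ser", "GCT"), ("Ser", "TGA"), ("Arg", "ACG"), ("Arg", "TCT"),
    ("Leu", "AAG"), ("Leu", "CAA"), ("Tyr", "GTA"), ("Ile", "AAT"),
    ("Ile", "TAT"), ("Val", "AAC"), ("Thr", "AGT"), ("Lys", "CTT"),
    ("Glu", "CTC"), ("Asp", "GTC"), ("Asn", "GTT"), ("Phe", "GAA"),
    ("His", "GTG"), ("Gln", "CTG"), ("Cys", "GCA"), ("Trp", "CCA"),
    ("eMet", "CAT"), ("iMet", "CAT"),
]


# ---------------------------------------------------------------------------
# Naive window scanners (ground-truth side; deliberately simple string code)
# ---------------------------------------------------------------------------

def _motif_positions(window: str, motifs: Sequence[str]) -> list[int]:
    """Start positions where at least one motif matches (overlaps allowed)."""
    hits = []
    for p in range(len(window)):
        for m in motifs:
            if window.startswith(m, p):
                hits.append(p)
                break
    return hits


def _t_runs(window: str, min_run: int = 4) -> list[tuple[int, int]]:
    """Maximal T-runs of length >= min_run as (offset, length), 5'->3'."""
    runs = []
    i = 0
    n = len(window)
    while i < n:
        if window[i] == "T":
            j = i
            while j < n and window[j] == "T":
                j += 1
            if j - i >= min_run:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# tRNA gene templates
# ---------------------------------------------------------------------------

def build_trna_template(isotype: str, anticodon: str, intron_length: int = 0,
                        seed: int = 0) -> tuple[str, SecondaryStructureRecord]:
    """Build a canonical cloverleaf tRNA gene for one isotype/anticodon.

    The mature template is 72 nt with stems of 7 (acceptor), 4 (D),
    5 (anticodon) and 5 (T) base pairs and a 4-nt variable loop; the
    requested anticodon sits at mature positions 34-36 (1-based).  Conserved
    internal-promoter residues are embedded: the A-box window (positions
    8-19) starts with T and ends with GG, the B-box window (positions 49-59)
    starts with GG and ends with CC.  An intron, when requested, is inserted
    after mature position 37 and carries a GCT prefix and a GAGT suffix
    mirroring the conservation seen in plant pre-tRNA introns.

    One fixed backbone is drawn per isotype for a given seed, so all
    isoacceptors of an isotype share a backbone and differ in the anticodon.
    Returns ``(gene_sequence, SecondaryStructureRecord)`` where the structure
    record describes the mature (intron-less) sequence.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or any(b not in BASES for b in anticodon):
        raise ValueError(f"anticodon must be a 3-mer over ACGT: {anticodon!r}")
    if intron_length != 0 and not (8 <= intron_length <= 200):
        raise ValueError(
            f"intron_length must be 0 or in [8, 200], got {intron_length}")

    rng = np.random.default_rng([int(seed) % (2 ** 31),
                                 zlib.crc32(isotype.encode())])
    seq = list(rng.choice(list(BASES), size=MATURE_LEN))
    for i, j in ALL_PAIRS:
        seq[j] = COMPLEMENT[seq[i]]
    # conserved residues (0-based): U8 spacer; D-loop G18 G19 (A-box T..GG)
    seq[7] = "T"
    seq[17], seq[18] = "G", "G"
    # B box GG..CC: positions 48/49 are T-stem pairs, keep partners paired
    seq[48], seq[62] = "G", "C"
    seq[49], seq[61] = "G", "C"
    seq[57], seq[58] = "C", "C"
    for pos, base in zip(ANTICODON_POSITIONS, anticodon):
        seq[pos] = base
    mature = "".join(seq)

    if intron_length:
        middle = "".join(rng.choice(list(BASES), size=intron_length - 7))
        intron = "GCT" + middle + "GAGT"
        gene = mature[:INTRON_INSERT_AFTER] + intron \
            + mature[INTRON_INSERT_AFTER:]
    else:
        gene = mature

    ss = SecondaryStructureRecord(
        gene_id=f"{isotype}-{anticodon}-template",
        sequence=mature,
        pairing=frozenset(ALL_PAIRS),
    )
    return gene, ss


def mutate_sequence(seq: str, n_subs: int, rng: np.random.Generator,
                    protected: Sequence[int] = ANTICODON_POSITIONS) -> str:
    """Apply ``n_subs`` random substitutions, avoiding protected positions."""
    if n_subs == 0:
        return seq
    eligible = [i for i in range(len(seq)) if i not in set(protected)]
    sites = rng.choice(eligible, size=min(n_subs, len(eligible)),
                       replace=False)
    chars = list(seq)
    for i in sites:
        chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


# ---------------------------------------------------------------------------
# Gene specifications and configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    """One planted gene family: identity, copies, layout, and flank elements.

    ``layout`` is one of ``scattered`` (each copy its own isolated locus),
    ``tandem`` (copies in one run separated by ``spacer_bp``), or
    ``alternating`` (pairs with ``partner``, i.e. ``copy_number`` pairs laid
    out A-B-A-B... with ``spacer_bp`` between neighbours).  ``upstream_motifs``
    are ``(motif, offset)`` with the motif start ``offset`` bases upstream of
    the gene start; ``downstream_t_runs`` are ``(length, offset)`` with the
    run starting ``offset`` bases after the gene end.  ``mutate_copies``
    substitutions are applied independently to every copy.
    """

    isotype: str
    anticodon: str
    strand: str = "+"
    copy_number: int = 1
    layout: str = "scattered"
    spacer_bp: int = 100
    partner: Optional["GeneSpec"] = None
    intron_length: int = 0
    upstream_motifs: tuple = ()
    downstream_t_runs: tuple = ()
    mutate_copies: int = 0
    score: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.layout not in ("scattered", "tandem", "alternating"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.layout == "alternating" and self.partner is None:
            raise ValueError("alternating layout requires a partner spec")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for motif, off in self.upstream_motifs:
            if not (len(motif) <= off <= UPSTREAM_SCAN):
                raise ValueError(
                    f"upstream motif {motif!r} at offset {off} does not fit "
                    f"the {UPSTREAM_SCAN}-nt upstream window")
        for length, off in self.downstream_t_runs:
            if length < 1 or off < 0 or off + length > DOWNSTREAM_SCAN:
                raise ValueError(
                    f"downstream T-run ({length}, {off}) does not fit the "
                    f"{DOWNSTREAM_SCAN}-nt downstream window")


@dataclass
class GenomeConfig:
    """Inputs for :func:`synthesize_genome`."""

    genome_id: str = "synth"
    lineage: str = "other"
    contig_lengths: dict = field(default_factory=lambda: {"chr1": 200_000})
    base_freqs: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
    gene_specs: list = field(default_factory=list)
    upstream_bp: int = 300    # reserved upstream flank per unit
    downstream_bp: int = 50
    tata_motifs: tuple = ("TATA",)
    min_t_run: int = 4
    cluster_gap_bp: int = 1000
    min_cluster_size: int = 3
    unit_separation_bp: int = 1500  # keeps units from merging into clusters
    template_seed: Optional[int] = None  # share templates across genomes


@dataclass
class PlantedGene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    sequence: str
    score: float
    note: str = ""
    intron_start: Optional[int] = None
    intron_end: Optional[int] = None
    intron_sequence: str = ""
    tata_count: int = 0
    caa_50: int = 0
    caa_10: int = 0
    t_runs: list = field(default_factory=list)


@dataclass
class TruthManifest:
    """Ground truth emitted alongside every synthetic genome."""

    genome_id: str
    seed: int
    genes: list = field(default_factory=list)          # PlantedGene
    clusters: list = field(default_factory=list)       # dicts
    unique_fraction_pct: Optional[float] = None
    distinct_count: int = 0
    total_genes: int = 0
    cohort_params: Optional[dict] = None

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        payload["genes"] = [PlantedGene(**g) for g in payload["genes"]]
        # JSON turns tuples into lists; normalize
        for g in payload["genes"]:
            g.t_runs = [tuple(r) for r in g.t_runs]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Unit assembly
# ---------------------------------------------------------------------------

class _Unit:
    """One placement unit: flanks + one or more genes with planted elements."""

    __slots__ = ("text", "genes")

    def __init__(self, text: str, genes: list):
        self.text = text
        self.genes = genes  # list of dicts with unit-relative coordinates


def _unit_gene_list(spec: GeneSpec) -> list[GeneSpec]:
    if spec.layout == "tandem":
        return [spec] * spec.copy_number
    if spec.layout == "alternating":
        return [spec, spec.partner] * spec.copy_number
    return [spec]


def _build_unit(specs: list[GeneSpec], spacer_bp: int, strand: str,
                config: GenomeConfig, rng: np.random.Generator,
                template_seed: int) -> _Unit:
    """Assemble one unit in sense orientation, then mirror if strand is '-'."""
    freqs = config.base_freqs
    probs = np.array([freqs.get(b, 0.0) for b in BASES], dtype=float)
    probs = probs / probs.sum()

    genes = []
    pos = config.upstream_bp
    for spec in specs:
        gene_seq, _ = build_trna_template(
            spec.isotype, spec.anticodon, spec.intron_length,
            seed=template_seed)
        gene_seq = mutate_sequence(gene_seq, spec.mutate_copies, rng)
        entry = {
            "spec": spec, "seq": gene_seq,
            "g0": pos, "g1": pos + len(gene_seq),
        }
        if spec.intron_length:
            i0 = pos + INTRON_INSERT_AFTER
            entry["intron"] = (i0, i0 + spec.intron_length)
        genes.append(entry)
        pos = entry["g1"] + spacer_bp
    unit_len = genes[-1]["g1"] + config.downstream_bp

    fixed: list[Optional[str]] = [None] * unit_len

    def plant(start: int, text: str, what: str) -> None:
        for k, ch in enumerate(text):
            cell = start + k
            if not (0 <= cell < unit_len):
                raise ValueError(f"{what} falls outside the unit")
            if fixed[cell] is not None and fixed[cell] != ch:
                raise ValueError(f"planted elements collide at {what}")
            fixed[cell] = ch

    for entry in genes:
        plant(entry["g0"], entry["seq"], "gene body")
        spec = entry["spec"]
        for motif, off in spec.upstream_motifs:
            plant(entry["g0"] - off, motif, f"upstream motif {motif!r}")
        for length, off in spec.downstream_t_runs:
            plant(entry["g1"] + off, "T" * length, "downstream T-run")

    # windows and skeleton-derived expected counts
    skel = "".join(c if c is not None else "N" for c in fixed)
    windows = []  # (lo, hi, gene index, kind)
    for gi, entry in enumerate(genes):
        up = (entry["g0"] - UPSTREAM_SCAN, entry["g0"])
        down = (entry["g1"], entry["g1"] + DOWNSTREAM_SCAN)
        w_up = skel[up[0]: up[1]]
        w_down = skel[down[0]: down[1]]
        entry["truth"] = {
            "tata": len(_motif_positions(w_up, config.tata_motifs)),
            "caa_50": len(_motif_positions(w_up, ["CAA"])),
            "caa_10": len(_motif_positions(w_up[-10:], ["CAA"])),
            "t_runs": _t_runs(w_down, config.min_t_run),
        }
        windows.append((up[0], up[1], gi, "up"))
        windows.append((down[0], down[1], gi, "down"))

    # merge overlapping constrained windows into regions
    windows.sort()
    regions: list[list] = []
    for lo, hi, gi, kind in windows:
        if regions and lo <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], hi)
            regions[-1][2].append((lo, hi, gi, kind))
        else:
            regions.append([lo, hi, [(lo, hi, gi, kind)]])

    final = list(fixed)

    def window_ok(lo: int, hi: int, gi: int, kind: str) -> bool:
        w = "".join(final[lo:hi])
        t = genes[gi]["truth"]
        if kind == "up":
            return (len(_motif_positions(w, config.tata_motifs)) == t["tata"]
                    and len(_motif_positions(w, ["CAA"])) == t["caa_50"]
                    and len(_motif_positions(w[-10:], ["CAA"])) == t["caa_10"])
        return _t_runs(w, config.min_t_run) == t["t_runs"]

    for lo, hi, members in regions:
        bg_cells = [i for i in range(lo, hi) if fixed[i] is None]
        for attempt in range(1000):
            draw = rng.choice(list(BASES), size=len(bg_cells), p=probs)
            for cell, ch in zip(bg_cells, draw):
                final[cell] = ch
            if all(window_ok(*w) for w in members):
                break
        else:
            raise RuntimeError(
                "could not sample a flank background matching the planted "
                "motif counts after 1000 attempts")

    free = [i for i in range(unit_len) if final[i] is None]
    if free:
        draw = rng.choice(list(BASES), size=len(free), p=probs)
        for cell, ch in zip(free, draw):
            final[cell] = ch
    text = "".join(final)

    out_genes = []
    for entry in genes:
        g = {
            "spec": entry["spec"], "seq": entry["seq"],
            "g0": entry["g0"], "g1": entry["g1"],
            "intron": entry.get("intron"), "truth": entry["truth"],
            "strand": strand,
        }
        out_genes.append(g)

    if strand == "-":
        text = revcomp(text)
        for g in out_genes:
            g["g0"], g["g1"] = unit_len - g["g1"], unit_len - g["g0"]
            if g["intron"] is not None:
                i0, i1 = g["intron"]
                g["intron"] = (unit_len - i1, unit_len - i0)
    return _Unit(text, out_genes)


def _pattern_label(isotypes: list[str]) -> str:
    kinds = sorted(set(isotypes), key=isotypes.index)
    if len(kinds) == 1:
        return f"homogeneous:{kinds[0]}"
    if len(kinds) == 2 and all(a != b for a, b in zip(isotypes, isotypes[1:])):
        return f"alternating:{kinds[0]}/{kinds[1]}"
    return "mixed"


# ---------------------------------------------------------------------------
# Genome synthesis
# ---------------------------------------------------------------------------

def synthesize_genome(config: GenomeConfig, seed: int
                      ) -> tuple[GenomeRecord, list[TRNAGeneRecord],
                                 TruthManifest]:
    """Generate one genome with planted tDNAs plus its truth manifest.

    Deterministic given ``seed``.  Units (isolated genes or whole cluster
    blocks) are placed on contigs with at least ``config.unit_separation_bp``
    between their envelopes, so genes of different units can never satisfy
    the cluster criterion together.  Raises when the requested genes cannot
    be placed in the configured contigs.
    """
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    template_seed = (config.template_seed
                     if config.template_seed is not None
                     else int(seed) % (2 ** 31))

    # build units
    units: list[_Unit] = []
    for spec in config.gene_specs:
        if spec.layout == "scattered":
            for _ in range(spec.copy_number):
                units.append(_build_unit([spec], 0, spec.strand, config, rng,
                                         template_seed))
        else:
            units.append(_build_unit(
                _unit_gene_list(spec), spec.spacer_bp, spec.strand, config,
                rng, template_seed))

    # assign units to contigs (probability proportional to length)
    contig_names = list(config.contig_lengths)
    lengths = np.array([config.contig_lengths[c] for c in contig_names],
                       dtype=float)
    unit_contigs = rng.choice(len(contig_names), size=len(units),
                              p=lengths / lengths.sum()) if units else []

    sep = config.unit_separation_bp
    placements: dict[int, int] = {}  # unit index -> absolute start
    for ci, cname in enumerate(contig_names):
        idx = [u for u in range(len(units)) if unit_contigs[u] == ci]
        rng.shuffle(idx)
        total = sum(len(units[u].text) for u in idx)
        clen = config.contig_lengths[cname]
        slack = clen - total - max(0, len(idx) - 1) * sep
        if slack < 0:
            raise RuntimeError(
                f"cannot place {len(idx)} gene units ({total} bp + spacing) "
                f"in contig {cname} of {clen} bp")
        gaps = np.sort(rng.integers(0, slack + 1, size=len(idx)))
        pos = 0
        prev_gap = 0
        for k, u in enumerate(idx):
            pos += int(gaps[k]) - prev_gap + (sep if k else 0)
            placements[u] = pos
            pos += len(units[u].text)
            prev_gap = int(gaps[k])

    # assemble contig sequences
    freqs = config.base_freqs
    probs = np.array([freqs.get(b, 0.0) for b in BASES], dtype=float)
    probs = probs / probs.sum()
    contigs: dict[str, str] = {}
    for ci, cname in enumerate(contig_names):
        arr = rng.choice(list(BASES), size=config.contig_lengths[cname],
                         p=probs)
        seq = list(arr)
        for u, start in placements.items():
            if unit_contigs[u] == ci:
                seq[start: start + len(units[u].text)] = units[u].text
        contigs[cname] = "".join(seq)

    genome = GenomeRecord(genome_id=config.genome_id, lineage=config.lineage,
                          contigs=contigs)

    # absolute gene coordinates, ids in per-contig positional order
    planted = []  # (contig, abs_start, gene dict, unit index)
    for u, start in placements.items():
        cname = contig_names[unit_contigs[u]]
        for g in units[u].genes:
            planted.append((cname, start + g["g0"], start + g["g1"], g, u))
    planted.sort(key=lambda t: (t[0], t[1]))

    counter: dict[str, int] = {}
    records: list[TRNAGeneRecord] = []
    truth_genes: list[PlantedGene] = []
    unit_members: dict[int, list] = {}
    for cname, a0, a1, g, u in planted:
        counter[cname] = counter.get(cname, 0) + 1
        gene_id = f"{cname}.trna{counter[cname]}"
        spec: GeneSpec = g["spec"]
        strand = g["strand"]
        locus = GeneLocus(cname, a0, a1, strand)
        intron = None
        istart = iend = None
        iseq = ""
        if g["intron"] is not None:
            off0, off1 = g["intron"]
            shift = a0 - g["g0"]
            intron = GeneLocus(cname, off0 + shift, off1 + shift, strand)
            istart, iend = intron.start, intron.end
            iseq = genome.fetch(intron)
        score = spec.score if spec.score is not None else round(
            float(rng.uniform(96.0, 120.0)), 1)
        rec = TRNAGeneRecord(
            gene_id=gene_id, locus=locus, isotype=spec.isotype,
            anticodon=spec.anticodon, intron=intron, score=score,
            note=spec.note, gene_sequence=genome.fetch(locus))
        assert rec.gene_sequence == g["seq"], "planted gene round-trip failed"
        records.append(rec)
        t = g["truth"]
        truth_genes.append(PlantedGene(
            gene_id=gene_id, contig=cname, start=a0, end=a1, strand=strand,
            isotype=spec.isotype, anticodon=spec.anticodon,
            sequence=g["seq"], score=score, note=spec.note,
            intron_start=istart, intron_end=iend, intron_sequence=iseq,
            tata_count=t["tata"], caa_50=t["caa_50"], caa_10=t["caa_10"],
            t_runs=list(t["t_runs"])))
        unit_members.setdefault(u, []).append((a0, a1, gene_id, spec.isotype))

    # expected clusters: multi-gene units whose spacing passes the criterion
    clusters = []
    for u, members in sorted(unit_members.items()):
        if len(members) < config.min_cluster_size:
            continue
        members.sort()
        gaps = [b[0] - a[1] for a, b in zip(members, members[1:])]
        if all(gap <= config.cluster_gap_bp for gap in gaps):
            clusters.append({
                "contig": contig_names[unit_contigs[u]],
                "start": members[0][0],
                "end": members[-1][1],
                "members": [m[2] for m in members],
                "pattern": _pattern_label([m[3] for m in members]),
            })
    clusters.sort(key=lambda c: (c["contig"], c["start"]))

    total = len(truth_genes)
    distinct = len({g.sequence for g in truth_genes})
    manifest = TruthManifest(
        genome_id=config.genome_id, seed=int(seed), genes=truth_genes,
        clusters=clusters,
        unique_fraction_pct=(100.0 * distinct / total) if total else None,
        distinct_count=distinct, total_genes=total)
    return genome, records, manifest


def mirror_genome(genome: GenomeRecord, records: Sequence[TRNAGeneRecord]
                  ) -> tuple[GenomeRecord, list[TRNAGeneRecord]]:
    """Reverse-complement every contig and flip all record strands.

    Sense-strand gene content is unchanged, so every per-gene report must be
    identical on the mirrored genome.
    """
    if genome.contigs is None:
        raise ValueError("cannot mirror a metadata-only genome")
    new_contigs = {name: revcomp(seq) for name, seq in genome.contigs.items()}
    mirrored = GenomeRecord(genome_id=genome.genome_id + "_rc",
                            lineage=genome.lineage, contigs=new_contigs)

    def flip(locus: GeneLocus) -> GeneLocus:
        length = len(genome.contigs[locus.contig])
        return GeneLocus(locus.contig, length - locus.end,
                         length - locus.start,
                         "-" if locus.strand == "+" else "+")

    new_records = []
    for rec in records:
        new_records.append(TRNAGeneRecord(
            gene_id=rec.gene_id, locus=flip(rec.locus), isotype=rec.isotype,
            anticodon=rec.anticodon,
            intron=flip(rec.intron) if rec.intron else None,
            score=rec.score, note=rec.note,
            gene_sequence=rec.gene_sequence))
    return mirrored, new_records


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: lineage proportions of the emulated survey (44 eudicots, 20 monocots,
#: 4 ANA, 1 Ceratophyllum out of 69 genomes)
STUDY_LINEAGE_COUNTS = {"eudicot": 44, "monocot": 20, "ANA": 4,
                        "Ceratophyllum": 1}


@dataclass
class Cohort:
    """A set of genomes with annotations (or counts only) plus truth."""

    genomes: list
    records: dict                 # genome_id -> list[TRNAGeneRecord]
    counts: dict                  # genome_id -> gene count
    manifests: dict               # genome_id -> TruthManifest (if material)
    params: dict                  # generating regression parameters


def _study_lineages(n: int) -> list[str]:
    labels = []
    for lab, k in STUDY_LINEAGE_COUNTS.items():
        labels.extend([lab] * max(1, round(k / 69 * n)))
    return labels[:n] + ["eudicot"] * max(0, n - len(labels))


def synthesize_cohort(n_genomes: int = 69,
                      size_range_mb: tuple[float, float] = (0.05, 0.5),
                      slope: float = 250.0,
                      intercept: float = 20.0,
                      noise_sd: float = 35.0,
                      lineages: Optional[Sequence[str]] = None,
                      seed: int = 0,
                      materialize: bool = False,
                      plant_shared: bool = True) -> Cohort:
    """Generate a cohort with a linear gene-count-vs-genome-size relation.

    Per genome, ``count = round(intercept + slope * size_Mb + N(0, sd))``
    floored at 1.  By default only metadata (declared sizes, counts, lineage
    labels) is produced, which is what the regression stage consumes; with
    ``materialize=True`` real sequences and annotations are generated at the
    declared sizes (keep sizes small), genes scattered, and one identical
    Ala-AGC gene planted in every genome when ``plant_shared``.
    """
    if n_genomes < 3:
        raise ValueError("a cohort needs at least 3 genomes")
    lo, hi = size_range_mb
    if lo == hi and noise_sd == 0:
        raise ValueError("degenerate size range with zero noise: "
                         "regression undefined")
    if intercept + slope * lo <= 0:
        raise ValueError("slope/intercept produce non-positive counts at the "
                         "lower end of the size range")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    sizes_mb = rng.uniform(lo, hi, size=n_genomes)
    noise = rng.normal(0.0, noise_sd, size=n_genomes) if noise_sd > 0 \
        else np.zeros(n_genomes)
    counts = np.maximum(
        1, np.rint(intercept + slope * sizes_mb + noise).astype(int))
    labels = list(lineages) if lineages is not None \
        else _study_lineages(n_genomes)
    if len(labels) != n_genomes:
        raise ValueError("lineages must have one label per genome")

    params = {"slope": slope, "intercept": intercept, "noise_sd": noise_sd,
              "n_genomes": n_genomes, "size_range_mb": list(size_range_mb),
              "seed": int(seed)}

    genomes: list[GenomeRecord] = []
    records: dict[str, list] = {}
    manifests: dict[str, TruthManifest] = {}
    count_map: dict[str, int] = {}
    for i in range(n_genomes):
        gid = f"genome{i + 1:03d}"
        size_bp = int(round(sizes_mb[i] * 1e6))
        count_map[gid] = int(counts[i])
        if not materialize:
            genomes.append(GenomeRecord(genome_id=gid, lineage=labels[i],
                                        contigs=None, size_bp=size_bp))
            continue
        specs = []
        remaining = int(counts[i])
        if plant_shared and remaining > 0:
            specs.append(GeneSpec("Ala", "AGC", copy_number=1,
                                  mutate_copies=0))
            remaining -= 1
        while remaining > 0:
            iso, ac = ISOACCEPTORS[int(rng.integers(len(ISOACCEPTORS)))]
            copies = 1 if rng.random() < 0.6 else int(rng.integers(2, 5))
            copies = min(copies, remaining)
            mut = 0 if rng.random() < 0.5 else 2
            strand = "+" if rng.random() < 0.5 else "-"
            specs.append(GeneSpec(iso, ac, strand=strand, copy_number=copies,
                                  mutate_copies=mut))
            remaining -= copies
        cfg = GenomeConfig(
            genome_id=gid, lineage=labels[i],
            contig_lengths={"chr1": size_bp},
            gene_specs=specs,
            template_seed=int(seed) % (2 ** 31))
        sub_seed = int(rng.integers(0, 2 ** 31))
        genome, recs, manifest = synthesize_genome(cfg, seed=sub_seed)
        manifest.cohort_params = params
        genomes.append(genome)
        records[gid] = recs
        manifests[gid] = manifest

    return Cohort(genomes=genomes, records=records, counts=count_map,
                  manifests=manifests, params=params)


def survey_genome_config(seed: int, genome_id: Optional[str] = None,
                         contig_bp: int = 200_000) -> GenomeConfig:
    """A randomized survey-like genome: 30-80 genes on a ~200 kb contig.

    Each draw plants one tandem Pro cluster, one alternating Tyr/Ser
    cluster, intron-bearing eMet and Tyr genes, and scattered genes on both
    strands with randomized upstream TATA/CAA motifs and downstream
    terminator (plus optional backup) T-runs - the feature mix a nuclear
    tDNA survey encounters.
    """
    rng = np.random.default_rng([int(seed) % (2 ** 31), 811])
    specs: list[GeneSpec] = []
    target = int(rng.integers(30, 81))

    tandem_n = int(rng.integers(3, 7))
    specs.append(GeneSpec(
        "Pro", "TGG", copy_number=tandem_n, layout="tandem",
        spacer_bp=int(rng.integers(100, 400)),
        downstream_t_runs=((int(rng.integers(4, 7)),
                            int(rng.integers(0, 10))),)))
    alt_pairs = int(rng.integers(2, 5))
    specs.append(GeneSpec(
        "Tyr", "GTA", copy_number=alt_pairs, layout="alternating",
        partner=GeneSpec("Ser", "AGA"),
        spacer_bp=int(rng.integers(100, 300)),
        strand="-" if rng.random() < 0.5 else "+"))
    specs.append(GeneSpec("eMet", "CAT", copy_number=2,
                          intron_length=int(rng.integers(8, 25))))
    specs.append(GeneSpec("Tyr", "GTA", copy_number=1, strand="-",
                          intron_length=int(rng.integers(8, 25))))
    total = tandem_n + 2 * alt_pairs + 3

    while total < target:
        iso, ac = ISOACCEPTORS[int(rng.integers(len(ISOACCEPTORS)))]
        copies = 1 if rng.random() < 0.7 else int(rng.integers(2, 4))
        copies = min(copies, target - total)
        ups = []
        if rng.random() < 0.5:  # TATA upstream, clear of the CAA zone
            ups.append(("TATA", int(rng.integers(25, 47))))
        if rng.random() < 0.5:
            ups.append(("CAA", int(rng.integers(3, 21))))
        downs = []
        if rng.random() < 0.7:
            off1, len1 = int(rng.integers(0, 12)), int(rng.integers(4, 8))
            downs.append((len1, off1))
            if rng.random() < 0.5:
                off2 = off1 + len1 + 1 + int(rng.integers(0, 10))
                len2 = int(rng.integers(4, 6))
                if off2 + len2 <= DOWNSTREAM_SCAN:
                    downs.append((len2, off2))
        specs.append(GeneSpec(
            iso, ac, strand="-" if rng.random() < 0.5 else "+",
            copy_number=copies, mutate_copies=int(rng.integers(0, 3)),
            upstream_motifs=tuple(ups), downstream_t_runs=tuple(downs),
            intron_length=int(rng.choice([0, 0, 0, 12]))))
        total += copies

    return GenomeConfig(genome_id=genome_id or f"survey{seed}",
                        contig_lengths={"chr1": contig_bp},
                        gene_specs=specs)


# ---------------------------------------------------------------------------
# Alignment simulators for covariation analysis
# ---------------------------------------------------------------------------

CANONICAL_PAIRS = ["AT", "TA", "GC", "CG", "GT", "TG"]


def simulate_paired_alignment(n_seqs: int, length: int,
                              pairs: Sequence[tuple[int, int]],
                              mode: str = "compensatory",
                              seed: int = 0) -> list[tuple[str, str]]:
    """Simulate an ungapped alignment with known pairing behaviour.

    ``compensatory`` draws each paired column pair jointly from the canonical
    pairable set (base pairing always preserved, partners co-vary);
    ``independent`` draws the two columns independently and uniformly
    (pairing frequently broken).  Unpaired columns are uniform i.i.d.
    """
    if mode not in ("compensatory", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    paired_positions = {p for ij in pairs for p in ij}
    rows = []
    for s in range(n_seqs):
        chars = [""] * length
        for i, j in pairs:
            if mode == "compensatory":
                pick = CANONICAL_PAIRS[int(rng.integers(6))]
                chars[i], chars[j] = pick[0], pick[1]
            else:
                chars[i] = BASES[int(rng.integers(4))]
                chars[j] = BASES[int(rng.integers(4))]
        for p in range(length):
            if p not in paired_positions:
                chars[p] = BASES[int(rng.integers(4))]
        rows.append((f"seq{s + 1}", "".join(chars)))
    return rows
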