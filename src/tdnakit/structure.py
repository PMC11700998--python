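"""Cloverleaf partitioning, internal promoter boxes, and covariation scores.

A canonical tRNA secondary structure has exactly four contiguous helices
(acceptor, D, anticodon, T stems in 5' order); helix detection forbids
bulges, and a structure with any other helix count fails loudly rather than
being guessed.  The A and B boxes - the internal RNA polymerase III promoter
elements overlapping the D- and T-arm sequences - are cut from the mature
sequence by fixed landmarks, and their generally conserved residues
(A box: 5' T ... 3' GG; B box: 5' GG ... 3' CC) are checked.

The covariation statistic for a reference pair (i, j) over an alignment is

    score = B - phi * q

where q is the fraction of sequences whose (i, j) bases cannot pair
(pairable set: AT/TA/GC/CG and the GT/TG wobble; gaps never pair), and B is
the mean Hamming distance between the (i, j) base pairs of the two members,
summed over unordered sequence pairs in which both members are pairable and
divided by C(N, 2).  Fully conserved pairs score 0, compensatory double
mutations push the score toward +2, pairing-disrupting mutations push it
toward -phi.  Positive scores mean base pairing is maintained by coordinated
substitution; negative scores mean mutations break the pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .io_formats import (
    SecondaryStructureRecord,
    TRNAGeneRecord,
    pairs_from_brackets,
)

PAIRABLE = {"AT", "TA", "GC", "CG", "GT", "TG"}

STEM_NAMES = ("acceptor", "D", "anticodon", "T")


class NonCanonicalStructureError(ValueError):
    """Raised when a structure does not partition into the four tRNA stems."""

    def __init__(self, n_helices: int):
        self.n_helices = n_helices
        super().__init__(
            f"structure has {n_helices} helices; a canonical cloverleaf "
            "has exactly 4 (acceptor, D, anticodon, T)")


@dataclass
class CloverleafPartition:
    """Stems (lists of base pairs) and loops (position ranges) of a tRNA."""

    stems: dict                  # name -> list[(i, j)]
    loops: dict                  # name -> range
    length: int

    @property
    def stem_lengths(self) -> dict:
        return {name: len(p) for name, p in self.stems.items()}

    @property
    def element_lengths(self) -> dict:
        out = {f"{name}_stem_bp": len(p) for name, p in self.stems.items()}
        out.update({f"{name}_loop_nt": len(r)
                    for name, r in self.loops.items()})
        out["trna_nt"] = self.length
        return out


@dataclass
class CovariationScore:
    pair: tuple
    score: float
    classification: str          # positive | negative | zero
    n_pairable: int
    n_nonpairable: int
    b_component: float
    q_component: float


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _helices(pairing: frozenset) -> list[list[tuple[int, int]]]:
    """Maximal stacked runs of pairs: (i+1, j-1) continues the helix of
    (i, j); any bulge breaks the run."""
    pairs = sorted(pairing)
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 \
                and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def partition_cloverleaf(ss: SecondaryStructureRecord) -> CloverleafPartition:
    """Partition a nested pairing into the four cloverleaf stems and loops.

    Helices are assigned acceptor, D, anticodon, T in 5' order of their 5'
    strands; loops are the unpaired gaps each helix encloses, plus the
    variable loop between the anticodon stem's 3' strand and the T stem's
    5' strand.
    """
    helices = _helices(ss.pairing)
    if len(helices) != 4:
        raise NonCanonicalStructureError(len(helices))
    helices.sort(key=lambda h: h[0][0])
    stems = dict(zip(STEM_NAMES, helices))

    def enclosed(helix: list[tuple[int, int]]) -> range:
        last_i = helix[-1][0]
        min_j = helix[-1][1]
        return range(last_i + 1, min_j)

    loops = {
        "D": enclosed(stems["D"]),
        "anticodon": enclosed(stems["anticodon"]),
        "T": enclosed(stems["T"]),
        "variable": range(max(j for _, j in stems["anticodon"]) + 1,
                          stems["T"][0][0]),
    }
    return CloverleafPartition(stems=stems, loops=loops,
                               length=len(ss.sequence))


# ---------------------------------------------------------------------------
# A / B boxes
# ---------------------------------------------------------------------------

@dataclass
class BoxReport:
    a_box: str
    b_box: str
    a_box_ok: bool               # starts with T, ends with GG
    b_box_ok: bool               # starts with GG, ends with CC


def extract_boxes(mature_sequence, partition: CloverleafPartition,
                  a_box_start: int = 8, a_box_len: int = 12,
                  b_box_offset: int = 1, b_box_len: int = 11) -> BoxReport:
    """Cut the A and B box windows from a mature (intron-less) sequence.

    The A box is the 12-nt window starting at mature position 8 (1-based);
    the B box is the 11-nt window starting one base after the first position
    of the T-stem 5' strand.  Both anchors are configurable offsets.  Accepts
    a plain mature string or a TRNAGeneRecord (spliced automatically).
    """
    if isinstance(mature_sequence, TRNAGeneRecord):
        mature = mature_sequence.mature_sequence()
    else:
        mature = str(mature_sequence)
    a0 = a_box_start - 1
    b0 = partition.stems["T"][0][0] + b_box_offset
    if a0 + a_box_len > len(mature) or b0 + b_box_len > len(mature):
        raise ValueError(
            f"mature sequence of {len(mature)} nt too short for the "
            "A/B box windows")
    a_box = mature[a0: a0 + a_box_len]
    b_box = mature[b0: b0 + b_box_len]
    return BoxReport(
        a_box=a_box, b_box=b_box,
        a_box_ok=a_box.startswith("T") and a_box.endswith("GG"),
        b_box_ok=b_box.startswith("GG") and b_box.endswith("CC"))


# ---------------------------------------------------------------------------
# Covariation
# ---------------------------------------------------------------------------

def covariation_scores(alignment: Sequence[tuple[str, str]],
                       reference_structure, phi: float = 1.0,
                       tol: float = 1e-12) -> list[CovariationScore]:
    """Score every reference base pair for covariation over an alignment.

    ``reference_structure`` is a dot-bracket string over alignment columns,
    or an iterable of 0-based column pairs.  See the module docstring for
    the statistic.
    """
    if not alignment:
        raise ValueError("alignment is empty")
    length = len(alignment[0][1])
    rows = [seq.upper().replace("U", "T") for _, seq in alignment]
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    if isinstance(reference_structure, str):
        ref_pairs = sorted(pairs_from_brackets(
            reference_structure, open_chars="(<", close_chars=")>"))
    else:
        ref_pairs = sorted(tuple(sorted(p)) for p in reference_structure)

    n = len(rows)
    total_pairs = n * (n - 1) / 2
    out: list[CovariationScore] = []
    for i, j in ref_pairs:
        if not (0 <= i < length and 0 <= j < length):
            raise ValueError(f"reference pair ({i},{j}) outside alignment "
                             f"of length {length}")
        duplets = [r[i] + r[j] for r in rows]
        pairable = [d for d in duplets if d in PAIRABLE]
        q = (n - len(pairable)) / n
        if total_pairs > 0:
            b_sum = sum(
                (a[0] != b[0]) + (a[1] != b[1])
                for a, b in combinations(pairable, 2))
            b = b_sum / total_pairs
        else:
            b = 0.0
        score = b - phi * q
        if score > tol:
            classification = "positive"
        elif score < -tol:
            classification = "negative"
        else:
            classification = "zero"
        out.append(CovariationScore(
            pair=(i, j), score=score, classification=classification,
            n_pairable=len(pairable), n_nonpairable=n - len(pairable),
            b_component=b, q_component=q))
    return out
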