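# Methods

This note documents the models, conventions, and parameter choices behind
`tdnakit`, and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based, half-open, with an explicit strand.
The tRNAscan-SE `.out` convention (1-based inclusive, minus strand encoded
by begin > end) is confined to its reader/writer, where the conversion is an
involution; a consequence of that convention is that a 1-bp interval cannot
be encoded (begin == end is strand-ambiguous), which the reader rejects.
The reader dispatches on column count, so both the plain and the extended
(`-H`-style) layouts parse; any trailing columns are preserved verbatim in
the record's note field. BED6 exports use the internal convention directly;
GFF3 shifts to 1-based inclusive at the file boundary and carries anticodon,
intron bounds, and notes as attributes, so GFF3 round-trips records fully
while BED6 round-trips the fields BED can represent (interval, strand,
isotype-anticodon name, score). Genomic sequences are stored as uppercase
DNA with U mapped to T; motif scanning is DNA-level.

## High-confidence filter

Annotations are filtered by Infernal bit score with an inclusive cutoff
(default 95, the post-filtering default for isotype-level confidence) and,
by default, records whose note contains a pseudogene flag are dropped. The
cutoff and flag handling are parameters, not policy: an empty result is
legal and logged.

## Uniqueness and cross-genome identity

A genome's unique-sequence percentage is 100 · distinct / total over full
genomic gene sequences — uppercase, sense strand, introns included. This is
the strictest reproducible definition; `include_introns=False` switches to
spliced sequences. Cross-genome conservation is exact string identity of
sense-strand gene sequences (a minus-strand copy matches a plus-strand
copy), reported with the isoacceptor and the carrier list.

## Regression

Gene counts are regressed on genome size in Mb by ordinary least squares;
the reported p-value is the two-sided t-test on the slope with n − 2 df
(equivalent to the F-test in simple regression). Groups with fewer than
three genomes are skipped with a warning; zero variance in size is an
error, and a constant response is reported as slope 0 with R² = 0 rather
than NaN. The 99% slope confidence interval uses the t distribution with
the OLS standard error.

## Cluster calling

Genes on a contig are sorted by start and merged single-linkage when the
gap from the running envelope end to the next start is ≤ `gap_bp`
(default 1000); overlapping or bookended genes always merge, matching
BEDTools `merge -d` semantics including the case of a long gene spanning
past its neighbours. Merged groups of ≥ 3 members are clusters. Strand is
ignored for merging. A `start_to_start` flag measures the criterion between
start coordinates instead, since the prose criterion "within 1 kb of each
other" admits either reading. Composition labels are isotype-level:
homogeneous (one isotype), alternating (exactly two isotypes, no adjacent
repeat — note the label's X/Y order follows start order, so it reverses
under coordinate mirroring), else mixed.

## Flank windows and motif scans

For a plus-strand gene, upstream windows are top-strand sequence
immediately left of the start and the downstream window immediately right
of the end; minus-strand genes mirror this by reverse complementation, so
every window reads 5'→3' on the gene's sense strand. Windows truncated at
contig edges are flagged and excluded from composition profiles.

TATA detection matches a configurable literal motif list (default the
4-mer `TATA`; an extended variant list ships in
`flanks.EXTENDED_TATA_MOTIFS`). A database-backed promoter scan is not
reproducible offline, so a declared motif list keeps the scan deterministic;
counts are occurrences at distinct start positions with overlaps allowed —
the simplest auditable convention. CAA is counted the same way over the
full −50..−1 window and over the 10 bases adjacent to the gene start
(inclusive of position −1). Poly(T) detection reports maximal runs of ≥ 4
Ts 5'→3'; the first run is the terminator, later runs are backups, and a
run touching the window edge is flagged as possibly truncated. The
aggregate mean terminator length uses first runs only; the length range
covers all qualifying runs. Windows are not masked against neighbouring
genes.

Composition profiles report per-position base frequencies, A+T fraction,
and information content 2 − H bits per column without small-sample
correction.

## Introns

Intron sequences are extracted strand-aware from their genomic loci.
Summaries give count/mean/min/max lengths per isotype and lineage, a
catalog of carriers outside the ubiquitous eMet/Tyr isotypes, and flags for
lengths above a configurable outlier threshold (default 50 bp, chosen
because observed plant pre-tRNA introns sit mostly at 10–20 bp with rare
outliers of 59–86 bp and above). Alignment-column conservation reports the
majority base per column with a gap-inclusive denominator, information
content over non-gap bases only (gaps reduce the effective support, which
is reported per column), and maximal runs of columns whose majority
frequency reaches the threshold (default 0.8 — an explicit numerical choice
standing in for by-eye logo inspection) as consensus motif spans.

## Cloverleaf partitioning and promoter boxes

Helices are maximal stacked runs of pairs with no bulges; tRNA stems are
canonically contiguous, so a structure that does not yield exactly four
helices raises a structured error naming the count instead of guessing.
Helices are assigned acceptor, D, anticodon, T in 5' order; loops are the
enclosed unpaired gaps plus the variable loop between the anticodon stem's
3' strand and the T stem's 5' strand. Stem lengths are reported in base
pairs, loops in nucleotides.

The A box is the 12-nt window starting at mature (intron-less) position 8;
the B box is the 11-nt window starting one base after the T-stem 5' strand.
Both anchors are configurable offsets, since box extraction in practice is
an alignment judgment call. The conserved-residue checks are A box
starting T and ending GG, B box starting GG and ending CC.

## Covariation

For a reference pair (i, j) over an alignment of N sequences:
q = fraction of sequences whose (i, j) bases are not in the pairable set
{AT, TA, GC, CG, GT, TG} (gaps never pair); B = Σ over unordered pairs of
pairable sequences of the Hamming distance between their two base pairs,
divided by C(N, 2); score = B − φ·q with φ = 1 by default. Scores lie in
[−φ, 2]; classification is by sign with a 1e-12 zero band. The statistic is
stated explicitly here because arc-diagram tools publish colors, not
formulas; only the sign is claimed to be comparable across tools.

## Duplication–loss reconciliation

Standard LCA parsimony on rooted binary trees: each gene node maps to the
species-tree LCA of its descendants' species; an internal node is a
duplication iff its mapping equals a child's mapping; losses on edge u→v
with species-path edge count d are d under a duplication at u and
max(d − 1, 0) under a speciation. This mapping provably minimizes the
duplication count, which the test suite verifies against an exhaustive
enumerator on small instances. Non-binary trees are rejected rather than
resolved, and branch lengths are ignored. Root-edge loss conventions differ
between reconciliation tools; the count here is the standard one above,
with no charge above the gene root. Gene leaves map to species by an
explicit table or, by default, by the label prefix up to the first
underscore.

## Synthetic data: what it emulates and what it does not

Templates are canonical 72-nt cloverleafs (stems 7/4/5/5 bp, variable loop
4 nt, anticodon at 34–36) with one fixed random backbone per isotype so
that ground truth stays computable; conserved promoter residues (A box
T…GG, B box GG…CC) are embedded, and introns insert after mature position
37 with a GCT prefix and GAGT suffix mirroring observed conservation. Any
isotype may carry an intron, emulating the rare non-Met/Tyr carriers.
Copy-level variation comes from a per-copy substitution count that never
touches the anticodon.

Genes are planted in placement units (an isolated gene, or a whole
tandem/alternating block) whose envelopes include the 300-nt upstream and
50-nt downstream flanks. Units are separated by ≥ 1.5 kb so genes of
different units can never co-cluster, making expected clusters a pure
function of the layout. Placement samples unit gaps from the available
slack, which succeeds whenever the genes fit and errors otherwise.

Expected motif counts are made exact by construction: a skeleton containing
only planted material (genes, motifs, T-runs) is scanned naively, and the
random background of each constrained flank window is rejection-sampled
(cap 1000 tries) until the assembled window's naive scan equals the
skeleton's. Everything outside the scanned windows is unconstrained i.i.d.
background. Minus-strand units are built in sense orientation and
reverse-complemented on insertion, so truth is strand-independent.

Cohorts draw genome sizes uniformly and set gene counts to
round(intercept + slope·size_Mb + N(0, sd)) floored at 1. The default
conditions (69 genomes, the 44/20/4/1 eudicot/monocot/ANA/Ceratophyllum
lineage split, slope 250 genes/Mb, intercept 20, noise sd 35) emulate a
plant-survey cohort at desk scale: sizes span 0.05–0.5 Mb rather than
hundreds of Mb so that materialized cohorts remain computable, with the
slope and noise chosen to give count ranges (~30–150) and an overall R² in
the regime such surveys report. By default only sizes and counts are
generated (all the regression consumes); `materialize=True` builds real
sequences with scattered genes, occasional identical duplicate copies, and
one identical Ala-AGC gene planted in every genome to emulate a strictly
conserved species. The survey-style generator (`survey_genome_config`)
draws 30–80 genes on a 200-kb contig with one tandem Pro cluster, one
alternating Tyr/Ser cluster, intron carriers, and randomized flank
elements.

Not emulated: genome evolution (the backbone is shared, not phylogenetic),
transposons, isochores, organellar genomes, pseudogenes with degenerate
structure, and accidental motif occurrences inside scanned windows (they
are excluded by the rejection step). Passing the planted-truth tests
therefore demonstrates that the pipeline measures exactly what is present,
not that real genomes look like the synthetic ones.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic instances sized
for a single CPU: 1,000 random layouts (≤ 200 genes) for the cluster
oracle, 20 survey-scale genomes (~200 kb, 30–80 genes) for planted-truth
recovery, 100 replicates of n = 200 cohorts for regression coverage,
exhaustive reconciliation instances up to 5–6 leaves, and 10,000 random
alignments for covariation bounds. All randomness flows through seeded
NumPy generators; pipeline reruns on the same inputs and seed are
byte-identical, and per-run parameters are recorded in the output
MANIFEST.
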