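"""Shared fixtures: a small synthetic genome with every planted feature."""

import pytest

from tdnakit.synthetic import GeneSpec, GenomeConfig, synthesize_genome


@pytest.fixture(scope="session")
def planted():
    """One genome exercising clusters, motifs, introns, strands, duplicates.

    Returns (genome, records, manifest).
    """
    specs = [
        GeneSpec("Pro", "TGG", copy_number=3, layout="tandem", spacer_bp=100,
                 upstream_motifs=(("TATA", 30), ("CAA", 8)),
                 downstream_t_runs=((5, 3), (4, 20))),
        GeneSpec("Tyr", "GTA", copy_number=4, layout="alternating",
                 partner=GeneSpec("Ser", "AGA"), spacer_bp=80, strand="-"),
        GeneSpec("eMet", "CAT", copy_number=2, intron_length=12,
                 downstream_t_runs=((6, 5),)),
        GeneSpec("Ala", "AGC", copy_number=5, mutate_copies=0),
        GeneSpec("Thr", "AGT", copy_number=1, strand="-", intron_length=15),
    ]
    config = GenomeConfig(genome_id="fixture", lineage="eudicot",
                          contig_lengths={"chr1": 120_000,
                                          "chr2": 80_000},
                          gene_specs=specs)
    return synthesize_genome(config, seed=20240)


@pytest.fixture()
def genome(planted):
    return planted[0]


@pytest.fixture()
def records(planted):
    return planted[1]


@pytest.fixture()
def manifest(planted):
    return planted[2]
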