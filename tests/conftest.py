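"""Shared fixtures: tiny deterministic genomes and annotation files."""

import numpy as np
import pytest

from mitoeditkit.synthetic_data import SimConfig, plant_edits, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but complete fixture config: 12-kb circle, 5 genes, one repeat."""
    return SimConfig(
        genome_length=12_000,
        n_genes=5,
        gene_length=(300, 600),
        repeat_length=800,
        edit_rate=8.0,
        n_transcripts=1,
        n_reads=0,
        seed=7,
    )


@pytest.fixture
def small_fixture(small_config):
    genome, truth = simulate_genome(small_config)
    cdnas = plant_edits(genome, truth, small_config)
    return genome, truth, cdnas


def write_genome_files(tmp_path, genome):
    """Write a genome fixture to FASTA + GFF3, returning the two paths."""
    from mitoeditkit.synthetic_data import write_fasta, write_gff3

    fasta = tmp_path / "genome.fasta"
    gff = tmp_path / "genome.gff3"
    write_fasta(fasta, [(genome.id, genome.sequence)])
    write_gff3(gff, genome)
    return fasta, gff
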