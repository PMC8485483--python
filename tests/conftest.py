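import numpy as np
import pytest

from paleostrain import SimParams, simulate_reads, simulate_strain_set
from paleostrain.alignment import ReadAlignment


def make_alignment(read_seq, ref_seq, ref_start=0, strand="+", mq=60,
                   read_id="r1", ref_id="ref"):
    """Ungapped ReadAlignment of read_seq placed at ref_start on ref_seq.

    read_seq is given in reference orientation (as stored in SAM).
    """
    pairs = [(i, ref_start + i, read_seq[i], ref_seq[ref_start + i])
             for i in range(len(read_seq))]
    return ReadAlignment(read_id, ref_id, ref_start, strand, mq, pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_strain_set():
    """One strain, error-free and damage-free reads at 10x: the perfect-data
    regime in which the consensus must reproduce the source genome."""
    params = SimParams(genome_length=20_000, n_species=1,
                       n_strains_per_species=1, seq_error=0.0,
                       damage_rate_5p=0.0, depth_per_strain=10.0, seed=11)
    genomes, truth = simulate_strain_set(params)
    reads, alignments = simulate_reads(genomes, truth, params)
    return params, genomes, truth, reads, alignments


@pytest.fixture(scope="session")
def damaged_read_set():
    """~50,000 damaged reads from one genome for damage-recovery checks."""
    params = SimParams(genome_length=100_000, n_species=1,
                       n_strains_per_species=1, seq_error=0.0,
                       damage_rate_5p=0.3, damage_decay=0.5,
                       depth_per_strain=31.0, seed=12)
    genomes, truth = simulate_strain_set(params)
    reads, alignments = simulate_reads(genomes, truth, params)
    return params, genomes, truth, reads, alignments
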