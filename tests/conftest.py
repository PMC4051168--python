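import numpy as np
import pytest

from oralcap import synthetic_data as sd
from oralcap.seqio import GenomeMeta, SequenceRecord


@pytest.fixture(scope="session")
def small_community():
    """Three toy genomes with distinct weights plus 1,500 simulated reads."""
    genomes, metas = sd.simulate_genomes(3, (4000, 6000), seed=101)
    spec = sd.CommunitySpec(
        members=tuple(zip(metas, (0.5, 0.3, 0.2))),
        read_length=100,
        error_rate=0.01,
        seed=102,
    )
    reads, truth = sd.simulate_reads(
        spec, {g.id: g for g in genomes}, n_reads=1500
    )
    return genomes, metas, spec, reads, truth


@pytest.fixture(scope="session")
def locus_sim():
    """One diploid paralogous locus simulation shared across tests."""
    spec = sd.DiploidLocusSpec(
        n_target_genes=2,
        n_homologues=2,
        paralogue_divergence=0.10,
        depth=40,
        gene_length=800,
        insert_mean=300,
        seed=7,
        absent_genes=(),
    )
    return spec, sd.simulate_paralogous_locus(spec)


def make_read(rid, seq, q=40):
    return SequenceRecord(id=rid, sequence=seq, qualities=(q,) * len(seq))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
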