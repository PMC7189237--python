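import pytest

from photognn.genome_io import Gene, Genome, SimilarityHit
from photognn.synthgen import SynthConfig, generate_collection, regenerate_fig1_toy


def make_gene(start, end, strand, gene_id, genome_id="G1", contig="chr1",
              protein_id=None):
    return Gene(
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        gene_id=gene_id,
        genome_id=genome_id,
        protein_id=protein_id or f"{gene_id}_p",
    )


def make_hit(q, s, evalue=1e-50, bitscore=200.0, identity=90.0, length=100,
             coverage=100.0):
    return SimilarityHit(
        query_id=q,
        subject_id=s,
        percent_identity=identity,
        alignment_length=length,
        evalue=evalue,
        bitscore=bitscore,
        query_coverage=coverage,
    )


@pytest.fixture(scope="session")
def fig1_toy():
    return regenerate_fig1_toy()


@pytest.fixture(scope="session")
def small_collection():
    """A reduced synthetic collection for fast unit/property tests."""
    cfg = SynthConfig(
        n_genomes=6, n_families=40, n_positive_families=8, seed=7
    )
    return generate_collection(cfg)
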