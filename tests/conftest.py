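import numpy as np
import pytest

from circseek.core import AnnotationSet, Exon, Gene, ReferenceGenome, Transcript
from circseek.simulate import SimConfig, generate_genome, plant_circrnas


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study conditions: 6 genes on 200 kb, 6 planted circles,
    2 tumour/normal pairs."""
    return SimConfig(genome_length=200_000, n_genes=6, n_circ_exonic=4,
                     n_circ_intergenic=2, n_pairs=2, depth_linear=5, rng_seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    genome, annotation = generate_genome(small_config)
    circs = plant_circrnas(genome, annotation, small_config)
    return genome, annotation, circs


def make_transcript(chrom="chr1", strand="+", gene_id="geneA",
                    transcript_id="geneA.t1", exon_coords=((0, 100), (200, 300))):
    exons = [Exon(s, e) for s, e in exon_coords]
    tx = Transcript(transcript_id, gene_id, chrom, strand, exons)
    gene = Gene(gene_id, chrom, strand, [tx])
    return gene, tx


def random_genome(length: int, seed: int, chrom="chr1") -> ReferenceGenome:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return ReferenceGenome({chrom: bytes(bases[rng.integers(0, 4, length)]).decode()})


@pytest.fixture
def toy_circle_genome():
    """400-nt genome with a circle planted at [100, 300) on +: AG just before
    100, GT just after 300. Returns (genome, start, end)."""
    genome = random_genome(400, seed=11)
    seq = bytearray(genome["chr1"], "ascii")
    seq[98:100] = b"AG"
    seq[300:302] = b"GT"
    genome.sequences["chr1"] = seq.decode()
    return genome, 100, 300
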