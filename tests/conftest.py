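import logging

import numpy as np
import pytest

from l1host import (
    GeneModel, GenomicInterval, L1Element, SimulationConfig,
    classify_l1_locations, simulate_genome,
)


@pytest.fixture(autouse=True)
def quiet_warnings(caplog):
    """Keep expected per-element warnings out of the test output noise."""
    logging.getLogger("l1host").setLevel(logging.ERROR)
    yield


def make_gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id, gene_id,
                     GenomicInterval(chrom, start, end, strand), strand)


def make_l1(l1_id, chrom, start, end, strand="+", **kwargs):
    return L1Element(l1_id, GenomicInterval(chrom, start, end, strand), strand, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome():
    cfg = SimulationConfig(seed=11, n_genes=120, n_intergenic_l1=60, chrom_count=2)
    genome = simulate_genome(cfg)
    l1s = classify_l1_locations(genome.l1s, genome.genes)
    return cfg, genome, l1s


def random_layout(rng, n_l1=200, n_genes=50, chroms=("chr1", "chr2", "chr3"), span=1_000_000):
    """Random overlapping-allowed gene and L1 intervals for oracle tests."""
    genes, l1s = [], []
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1_000, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", str(rng.choice(chroms)), start, start + length, strand))
    for i in range(n_l1):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 8_000))
        strand = "+" if rng.random() < 0.5 else "-"
        l1s.append(make_l1(f"l{i}", str(rng.choice(chroms)), start, start + length, strand))
    return genes, l1s
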