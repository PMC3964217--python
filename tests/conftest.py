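import numpy as np
import pandas as pd
import pytest

from etsgeo.annotation import GeneRecord
from etsgeo.synth import SynthConfig, generate_annotation, plant_motifs


def make_reads(rows):
    """BED6 read DataFrame from (chrom, start, end, strand) tuples."""
    return pd.DataFrame(
        [(c, s, e, ".", 0, st) for c, s, e, st in rows],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def uniform_reads(rng, n, genome_len, read_len=50, chrom="chr1"):
    starts = rng.integers(0, genome_len - read_len, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "name": ".",
            "score": 0,
            "strand": strands,
        }
    )


@pytest.fixture(scope="session")
def small_synth():
    """A small deterministic synthetic annotation with planted motifs."""
    cfg = SynthConfig(n_genes=150)
    genes, chrom_lengths = generate_annotation(cfg, seed=11)
    genome, promoters, truth = plant_motifs(cfg, genes, chrom_lengths, seed=12)
    return cfg, genes, chrom_lengths, genome, promoters, truth


@pytest.fixture
def gene_grid():
    """Hand-built genes exercising both pair geometries on one chromosome."""
    return [
        GeneRecord("gA", "chr1", "-", 1000),
        GeneRecord("gB", "chr1", "+", 1500),  # bidirectional with gA, d=500
        GeneRecord("gC", "chr1", "+", 10000),
        GeneRecord("gD", "chr1", "-", 10600),  # face-to-face with gC, d=600
        GeneRecord("gE", "chr1", "-", 20000),
        GeneRecord("gF", "chr1", "+", 21100),  # 1100 apart: no pair
        GeneRecord("gG", "chr2", "+", 5000),  # lone gene, other chromosome
    ]
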