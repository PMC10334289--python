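import numpy as np
import pandas as pd
import pytest

from dipsig.io import GenomeModel, TagSet


@pytest.fixture
def genome():
    return GenomeModel((("chr1", 1_000_000),))


@pytest.fixture
def two_chrom_genome():
    return GenomeModel((("chr1", 500_000), ("chr2", 500_000)))


def make_tagset(genome, starts, chrom="chr1", sample_id="s1", assay="5hmC", tag_len=36):
    starts = np.asarray(starts, dtype=np.int64)
    length = genome.lengths[chrom]
    ends = np.minimum(starts + tag_len, length)
    tags = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": np.maximum(ends, starts + 1),
            "strand": "+",
        }
    )
    return TagSet(sample_id=sample_id, assay=assay, genome=genome, tags=tags)


@pytest.fixture
def tagset_factory():
    return make_tagset


@pytest.fixture
def gene_table():
    rows = [
        ("g1", "GeneA", "chr1", "+", 100_000, 110_000),
        ("g2", "GeneB", "chr1", "-", 200_000, 206_000),
        ("g3", "GeneC", "chr1", "+", 300_000, 302_000),
    ]
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"])
    genes["length"] = genes["tx_end"] - genes["tx_start"]
    return genes
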