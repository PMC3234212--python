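import numpy as np
import pandas as pd
import pytest

from nascentmetrics.genes import GeneModel
from nascentmetrics.tags import TagLibrary


def make_library(tag_tuples, read_length=25, fragment_length=None, stranded=True):
    """Build a TagLibrary from (chrom, pos, strand) tuples."""
    if tag_tuples:
        df = pd.DataFrame(tag_tuples, columns=["chrom", "pos", "strand"])
    else:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "pos": pd.Series(dtype=np.int64),
                           "strand": pd.Series(dtype=str)})
    return TagLibrary(df, read_length=read_length, fragment_length=fragment_length,
                      stranded=stranded)


@pytest.fixture
def plus_gene():
    """10-kb plus-strand gene with two introns, TSS at 10000."""
    return GeneModel("gplus", "chr1", "+", 10_000, 20_000,
                     ((10_000, 12_000), (14_000, 16_000), (18_000, 20_000)))


@pytest.fixture
def minus_gene():
    """10-kb minus-strand gene with two introns, TSS at 29999."""
    return GeneModel("gminus", "chr1", "-", 20_000, 30_000,
                     ((20_000, 22_000), (24_000, 26_000), (28_000, 30_000)))
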