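import numpy as np
import pandas as pd
import pytest

from chromenv.genome import GenomeAssembly, PeakSet, make_gene


@pytest.fixture
def toy_assembly():
    return GenomeAssembly([("chr1", 100_000), ("chr2", 50_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals_frame(rng, n, chrom="chr1", length=10_000, max_len=400):
    starts = rng.integers(0, length - max_len, size=n)
    lens = rng.integers(1, max_len, size=n)
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lens})
    return df.drop_duplicates(["chrom", "start", "end"]).reset_index(drop=True)


@pytest.fixture
def toy_genes():
    return [
        make_gene("gA", "chr1", 10_000, 20_000, "+"),
        make_gene("gB", "chr1", 40_000, 45_000, "-", "lncRNA"),
        make_gene("gC", "chr2", 5_000, 9_000, "+"),
    ]
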