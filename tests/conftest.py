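import numpy as np
import pandas as pd
import pytest

from dilutionlab.rnaseq import CountMatrix, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_counts():
    """3 genes x 3 samples with unit-friendly lengths and spike totals."""
    genes = pd.Index(["geneA", "geneB", "geneC"], name="gene")
    samples = pd.Index(["s1", "s2", "s3"], name="sample")
    counts = pd.DataFrame(
        [[10, 10, 10], [2, 2, 2], [100, 1, 100]],
        index=genes,
        columns=samples,
    )
    return CountMatrix(
        counts=counts,
        lengths=pd.Series([1000, 1000, 1000], index=genes),
        spike_reads=pd.Series([1_000_000] * 3, index=samples),
    )


def make_normalized(values: dict, samples=None) -> NormalizedMatrix:
    """NormalizedMatrix from {gene: [values per sample]}."""
    df = pd.DataFrame.from_dict(values, orient="index")
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index.name = "gene"
    return NormalizedMatrix(values=df)
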