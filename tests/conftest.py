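import numpy as np
import pandas as pd
import pytest

from sernacall.intervals import EnhancerLocus, GeneLocus, GenomicInterval
from sernacall.matrix import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_enhancer(chrom, start, end):
    return EnhancerLocus(GenomicInterval(chrom, start, end))


def make_gene(symbol, chrom, start, end):
    return GeneLocus(symbol, GenomicInterval(chrom, start, end))


def random_enhancers(rng, n, chroms=("chr1", "chr2"), max_pos=500_000, width=300):
    """Random enhancer loci with distinct ids (duplicates dropped)."""
    out, seen = [], set()
    while len(out) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        key = (chrom, start)
        if key in seen:
            continue
        seen.add(key)
        out.append(make_enhancer(chrom, start, start + width))
    return out


def random_genes(rng, n, chroms=("chr1", "chr2"), max_pos=500_000, width=2_000):
    return [
        make_gene(
            f"G{i}",
            chroms[int(rng.integers(len(chroms)))],
            start := int(rng.integers(0, max_pos)),
            start + width,
        )
        for i in range(n)
    ]


def expr_from_rows(rows: dict, samples, meta=None):
    df = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(df, meta)


@pytest.fixture
def tiny_expr():
    meta = pd.DataFrame(
        {"cell_type": ["A", "A", "B", "B"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 10.0, 100.0], [5.0, 5.0, 5.0, 5.0]],
        index=["chr1:100-400", "chr1:10000-10300", "chr2:50-350"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df, meta)
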