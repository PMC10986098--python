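import numpy as np
import pandas as pd
import pytest

from nucleoshift import GenomeIndex


def make_fragments(rows):
    """Fragment table from (chrom, start, end) tuples."""
    if not rows:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.astype({"start": np.int64, "end": np.int64})


def make_regions(rows):
    """Region table from (chrom, start, end[, name[, score[, strand]]]) tuples."""
    out = []
    for r in rows:
        r = tuple(r) + (".", 0, ".")[len(r) - 3:]
        out.append(r)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "name",
                                      "score", "strand"])


@pytest.fixture
def two_chrom_genome():
    return GenomeIndex(["chr1", "chr2"], [100_000, 50_000])


@pytest.fixture
def seq_genome():
    seqs = {"chrA": "ACGT" * 2500, "chrB": "AT" * 5000}
    return GenomeIndex(["chrA", "chrB"], [10_000, 10_000], sequences=seqs)
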