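"""Fold enrichment of an interval set in annotation regions versus chance.

The chance model re-places each query interval uniformly at random on its
own chromosome, preserving length (optionally avoiding excluded regions by
rejection sampling). Pooled shuffles give the random-overlap counts of a
2×2 table on which a two-sided Fisher exact test is computed; the fold is
the ratio of observed to random overlap rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import IntervalIndex
from .io_formats import GenomeIndex

logger = logging.getLogger("nucleoshift")


@dataclass
class EnrichmentResult:
    n_query: int
    n_overlapping: int
    n_random_total: int
    n_random_overlapping: int
    fold: float
    p_value: float
    seed: int
    n_shuffles: int

    @property
    def table(self) -> list[list[int]]:
        return [[self.n_overlapping, self.n_query - self.n_overlapping],
                [self.n_random_overlapping,
                 self.n_random_total - self.n_random_overlapping]]


def shuffle_intervals(query: pd.DataFrame, genome: GenomeIndex,
                      seed: int | np.random.Generator = 0,
                      excluded: pd.DataFrame | None = None,
                      max_attempts: int = 1000) -> pd.DataFrame:
    """Length-preserving uniform re-placement on the same chromosome.

    An interval exactly as long as its chromosome is forcibly placed at 0.
    With *excluded* regions, rejection sampling retries up to
    *max_attempts* times per interval before raising.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl_index = IntervalIndex(excluded) if excluded is not None and len(excluded) else None
    chroms = query["chrom"].to_numpy()
    lengths = (query["end"] - query["start"]).to_numpy(np.int64)
    starts = np.empty(len(query), dtype=np.int64)
    for i in range(len(query)):
        chrom_len = genome.length(chroms[i])
        L = int(lengths[i])
        if L > chrom_len:
            raise ValueError(f"interval of length {L} exceeds chromosome "
                             f"{chroms[i]} ({chrom_len} bp)")
        for attempt in range(max_attempts):
            s = 0 if L == chrom_len else int(rng.integers(0, chrom_len - L + 1))
            if excl_index is None:
                break
            cs, ce = excl_index.candidates(chroms[i], s, s + L)
            if len(cs) == 0 or not np.any(np.minimum(ce, s + L) > np.maximum(cs, s)):
                break
        else:
            raise RuntimeError(f"shuffle_intervals: could not place interval {i} "
                               f"after {max_attempts} attempts")
        starts[i] = s
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths})


def count_overlapping(query: pd.DataFrame, reference: pd.DataFrame) -> int:
    """Number of query intervals with >= 1 bp overlap with any reference."""
    if len(query) == 0 or len(reference) == 0:
        return 0
    index = IntervalIndex(reference)
    chroms = query["chrom"].to_numpy()
    starts = query["start"].to_numpy(np.int64)
    ends = query["end"].to_numpy(np.int64)
    n = 0
    for i in range(len(query)):
        cs, ce = index.candidates(chroms[i], starts[i], ends[i])
        if len(cs) and np.any(np.minimum(ce, ends[i]) > np.maximum(cs, starts[i])):
            n += 1
    return n


def fisher_enrichment(query: pd.DataFrame, reference: pd.DataFrame,
                      genome: GenomeIndex, seed: int = 0, n_shuffles: int = 10,
                      excluded: pd.DataFrame | None = None) -> EnrichmentResult:
    """Fold enrichment of *query* in *reference* versus shuffled placement.

    With a = observed overlapping queries and R = summed overlapping
    intervals over *n_shuffles* shuffles, fold = (a/|query|) /
    (R/(|query|·n_shuffles)); the two-sided Fisher exact test is applied to
    the pooled table [[a, |query|−a], [R, |query|·n_shuffles − R]]. Zero
    random overlap reports fold +inf with the p-value from the same table.
    """
    if len(query) == 0:
        raise ValueError("fisher_enrichment requires a non-empty query set")
    rng = np.random.default_rng(seed)
    a = count_overlapping(query, reference)
    random_overlap = 0
    for _ in range(n_shuffles):
        shuffled = shuffle_intervals(query, genome, seed=rng, excluded=excluded)
        random_overlap += count_overlapping(shuffled, reference)
    n_random_total = len(query) * n_shuffles
    if random_overlap > 0:
        fold = (a / len(query)) / (random_overlap / n_random_total)
    else:
        fold = float("inf") if a > 0 else float("nan")
    table = [[a, len(query) - a],
             [random_overlap, n_random_total - random_overlap]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    result = EnrichmentResult(n_query=len(query), n_overlapping=a,
                              n_random_total=n_random_total,
                              n_random_overlapping=random_overlap,
                              fold=float(fold), p_value=float(p),
                              seed=seed, n_shuffles=n_shuffles)
    logger.info("fisher_enrichment: fold=%.3f p=%.3g (a=%d/%d, random %d/%d)",
                result.fold, result.p_value, a, len(query),
                random_overlap, n_random_total)
    return result
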