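"""Fragment-level transformations.

Size fractionation, dyad (fragment midpoint) computation, dyad pileup
tracks and their stacking filter, per-chromosome read capping, GC window
classification, per-length fragment GC and per-region fragment density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeIndex

logger = logging.getLogger("nucleoshift")

#: The study's five fragment-size fractions, lower-inclusive / upper-exclusive
#: so adjacent bins are disjoint; they partition [100, 200).
DEFAULT_SIZE_BINS: tuple[tuple[int, int], ...] = (
    (100, 120), (120, 140), (140, 160), (160, 180), (180, 200))

#: Mono-nucleosome analysis band used for classification and NRL work.
ANALYSIS_BAND: tuple[int, int] = (120, 180)


def fragment_lengths(fragments: pd.DataFrame) -> np.ndarray:
    return (fragments["end"] - fragments["start"]).to_numpy()


def filter_by_size(fragments: pd.DataFrame, size_bin: tuple[int, int]) -> pd.DataFrame:
    """Keep exactly the fragments with low <= length < high; order preserved."""
    low, high = size_bin
    if low >= high:
        raise ValueError(f"invalid size bin [{low}, {high})")
    length = fragments["end"] - fragments["start"]
    return fragments.loc[(length >= low) & (length < high)].reset_index(drop=True)


def compute_dyad(start: int, end: int) -> int:
    """Dyad = floor midpoint, ``start + (end - start) // 2``.

    Even-length fragments have no central base pair; the floor rule is a
    fixed convention so downstream phaseograms are exactly reproducible.
    """
    return start + (end - start) // 2


def dyad_positions(fragments: pd.DataFrame) -> np.ndarray:
    """Vectorised dyads for a fragment table."""
    start = fragments["start"].to_numpy()
    end = fragments["end"].to_numpy()
    return start + (end - start) // 2


@dataclass
class DyadTrack:
    """Per-chromosome sparse pileup of fragment dyads.

    ``data`` maps chromosome name to a pair of equal-length arrays
    (sorted unique positions, counts >= 1); ``total`` equals the number of
    contributing fragments.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_fragments(cls, fragments: pd.DataFrame) -> "DyadTrack":
        track = cls()
        if len(fragments) == 0:
            return track
        dyads = dyad_positions(fragments)
        for chrom, idx in fragments.groupby("chrom", sort=True).indices.items():
            pos, cnt = np.unique(dyads[idx], return_counts=True)
            track.data[str(chrom)] = (pos.astype(np.int64), cnt.astype(np.int64))
        return track

    @property
    def total(self) -> int:
        return int(sum(c.sum() for _, c in self.data.values()))

    def chromosomes(self) -> list[str]:
        return list(self.data.keys())


def build_dyad_track(fragments: pd.DataFrame) -> DyadTrack:
    """Materialise per-position dyad counts; sum of counts = fragment count."""
    return DyadTrack.from_fragments(fragments)


def drop_stacked_positions(track: DyadTrack, max_per_bp: int = 50) -> DyadTrack:
    """Discard positions where more than *max_per_bp* dyads pile up.

    The whole position is removed (not capped): such towers reflect
    amplification or mapping artefacts, not nucleosome spacing. Positions
    with exactly *max_per_bp* dyads are kept (strictly "more than").
    Idempotent; never increases any count.
    """
    if max_per_bp < 1:
        raise ValueError("max_per_bp must be >= 1")
    out = DyadTrack()
    removed = 0
    for chrom, (pos, cnt) in track.data.items():
        keep = cnt <= max_per_bp
        removed += int((~keep).sum())
        if keep.any():
            out.data[chrom] = (pos[keep], cnt[keep])
    if removed:
        logger.info("drop_stacked_positions: removed %d position(s) above %d",
                    removed, max_per_bp)
    return out


def cap_reads_per_chromosome(fragments: pd.DataFrame,
                             max_reads: int = 40_000_000,
                             seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Uniform per-chromosome subsample to at most *max_reads* fragments.

    Chromosomes at or under the cap pass through intact; otherwise exactly
    *max_reads* fragments are drawn without replacement, reproducibly under
    *seed*. Idempotent for a given cap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for chrom, idx in fragments.groupby("chrom", sort=True).indices.items():
        if len(idx) <= max_reads:
            keep_idx.append(np.sort(idx))
        else:
            chosen = rng.choice(idx, size=max_reads, replace=False)
            keep_idx.append(np.sort(chosen))
    if not keep_idx:
        return fragments.copy()
    return fragments.iloc[np.concatenate(keep_idx)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# GC operations
# ---------------------------------------------------------------------------

def _gc_and_valid(seq: str) -> tuple[int, int]:
    """(#G+#C, #non-N) for a sequence; case-insensitive, N excluded."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    gc = int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
    valid = int(np.count_nonzero(arr != ord("N")))
    return gc, valid


@dataclass
class GcWindowSet:
    """Genome tiling into fixed windows labelled low-GC / high-GC."""

    window: int
    threshold: float
    table: pd.DataFrame  # chrom, start, end, gc, label

    def labelled(self, label: str) -> pd.DataFrame:
        return self.table.loc[self.table["label"] == label].reset_index(drop=True)


def gc_windows(genome: GenomeIndex, window: int = 10_000,
               threshold: float = 0.40) -> GcWindowSet:
    """Tile each chromosome into non-overlapping windows and label them by GC.

    GC = (#G + #C) / (#non-N bases); a window is low-GC when GC < threshold
    (strict), high-GC otherwise; all-N windows are left unlabelled. The
    final partial tile is kept only when it is at least half a window long.
    """
    rows = []
    for chrom in genome.names:
        length = genome.length(chrom)
        start = 0
        while start < length:
            end = min(start + window, length)
            if end - start < window and end - start < window / 2:
                break
            gc, valid = _gc_and_valid(genome.sequence(chrom, start, end))
            if valid == 0:
                rows.append((chrom, start, end, np.nan, "unlabelled"))
            else:
                frac = gc / valid
                rows.append((chrom, start, end, frac,
                             "low-GC" if frac < threshold else "high-GC"))
            start += window
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "label"])
    return GcWindowSet(window=window, threshold=threshold, table=table)


def fragment_gc_by_length(fragments: pd.DataFrame, genome: GenomeIndex) -> pd.Series:
    """Mean GC fraction of fragment sequences, per observed fragment length.

    N bases are excluded from both numerator and denominator; fragments that
    are entirely N contribute nothing.
    """
    lengths = fragment_lengths(fragments)
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom, start, end, length in zip(fragments["chrom"], fragments["start"],
                                         fragments["end"], lengths):
        gc, valid = _gc_and_valid(genome.sequence(chrom, start, end))
        if valid == 0:
            continue
        sums[length] = sums.get(length, 0.0) + gc / valid
        counts[length] = counts.get(length, 0) + 1
    out = pd.Series({l: sums[l] / counts[l] for l in sorted(sums)}, dtype=float)
    out.index.name = "length"
    return out


# ---------------------------------------------------------------------------
# per-region fragment density
# ---------------------------------------------------------------------------

def region_fragment_density(fragments: pd.DataFrame,
                            regions: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kb for every region, counting a fragment by its dyad.

    density(r) = #{fragments with dyad in [r.start, r.end)} / (len(r)/1000).
    Returns *regions* with added ``n_fragments`` and ``density`` columns.
    """
    dyads_by_chrom: dict[str, np.ndarray] = {}
    if len(fragments):
        d = dyad_positions(fragments)
        for chrom, idx in fragments.groupby("chrom", sort=True).indices.items():
            dyads_by_chrom[str(chrom)] = np.sort(d[idx])
    n = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.itertuples(index=False)):
        dy = dyads_by_chrom.get(row.chrom)
        if dy is None:
            continue
        n[i] = np.searchsorted(dy, row.end, "left") - np.searchsorted(dy, row.start, "left")
    out = regions.copy().reset_index(drop=True)
    out["n_fragments"] = n
    out["density"] = n / ((out["end"] - out["start"]) / 1000.0)
    return out


def select_extreme_regions(scored: pd.DataFrame, k: int, column: str = "density",
                           top: bool = True) -> pd.DataFrame:
    """Top-k (or bottom-k) regions by a score column; stable order on ties."""
    df = scored.sort_values(column, ascending=not top, kind="mergesort")
    return df.head(k).reset_index(drop=True)
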