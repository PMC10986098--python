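"""Nucleosome repeat length (NRL) estimation.

The estimator follows the dyad-distance route: build the *phaseogram* — the
frequency distribution of pairwise dyad–dyad distances at single-bp
resolution, per chromosome and then averaged — detect the peaks of its
oscillation (which sit near integer multiples of the repeat length), and
regress peak position on peak order. The slope of that regression is the
NRL in bp; a free intercept absorbs any constant offset of the first peak,
and R² is reported so callers can gate on fit quality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragment_ops import (DyadTrack, build_dyad_track, cap_reads_per_chromosome,
                           drop_stacked_positions, dyad_positions, filter_by_size)
from .io_formats import GenomeIndex

logger = logging.getLogger("nucleoshift")


class InsufficientDataError(RuntimeError):
    """No chromosome provides enough dyad pairs for a phaseogram."""


class TooFewPeaksError(RuntimeError):
    """Fewer than three phaseogram peaks: no NRL regression possible."""


@dataclass
class PhaseogramConfig:
    """Parameters of phaseogram construction and peak fitting.

    ``max_distance`` bounds the dyad–dyad distances counted (bp);
    ``stacked_read_cutoff`` discards base pairs carrying more dyads than
    that; ``chromosome_read_cap`` subsamples very deep chromosomes;
    chromosomes with fewer than ``min_pairs`` distance pairs are excluded
    from the genome average. Peak detection smooths the averaged curve with
    a centred moving average of half-width ``smoothing_half_width`` bp and
    enforces ``min_peak_separation`` between accepted peaks inside
    ``search_range``; at most ``max_peaks`` peaks enter the regression.
    """

    max_distance: int = 2000
    stacked_read_cutoff: int = 50
    chromosome_read_cap: int = 40_000_000
    min_pairs: int = 10_000
    smoothing_half_width: int = 10
    min_peak_separation: int = 100
    search_range: tuple[int, int] | None = (100, None)  # None upper -> max_distance
    max_peaks: int = 10
    min_prominence_fraction: float = 0.05
    peak_spacing_tolerance: float = 0.4  # harmonic consistency gate; 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_distance < 2:
            raise ValueError("max_distance must be >= 2")
        if self.smoothing_half_width >= self.min_peak_separation:
            raise ValueError("smoothing half-width must be < min peak separation")

    @property
    def resolved_search_range(self) -> tuple[int, int]:
        lo, hi = self.search_range if self.search_range else (1, None)
        return (max(1, lo), self.max_distance if hi is None else min(hi, self.max_distance))


@dataclass
class Phaseogram:
    """Dyad–dyad distance frequencies, per chromosome and genome-averaged.

    ``counts[c][d]`` (d = 0..D) holds raw pair counts for chromosome c;
    index 0 stores co-located pairs, which are excluded from normalisation
    (they reflect stacking, not spacing). ``frequency`` holds per-chromosome
    distributions over d = 1..D each summing to 1, and ``mean_frequency``
    their unweighted mean over the included chromosomes.
    """

    max_distance: int
    counts: dict[str, np.ndarray]
    frequency: dict[str, np.ndarray]
    mean_frequency: np.ndarray
    n_pairs: dict[str, int]
    included: list[str]

    @property
    def distances(self) -> np.ndarray:
        return np.arange(1, self.max_distance + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"distance": self.distances,
                           "mean_frequency": self.mean_frequency})
        for chrom in self.included:
            df[chrom] = self.frequency[chrom]
        return df


def _pair_counts(pos: np.ndarray, cnt: np.ndarray, max_distance: int,
                 block_pairs: int = 20_000_000) -> np.ndarray:
    """Exact pair-distance counts for one chromosome.

    counts[d] = sum over position pairs i<j with pos[j]-pos[i] = d <= D of
    cnt[i]*cnt[j]; counts[0] = sum of within-position pairs c*(c-1)/2.
    Processes in blocks to bound memory; products are exact in float64 for
    any realistic pileup.
    """
    D = int(max_distance)
    out = np.zeros(D + 1, dtype=np.int64)
    out[0] = int((cnt.astype(np.int64) * (cnt - 1) // 2).sum())
    n = len(pos)
    if n < 2:
        return out
    hi = np.searchsorted(pos, pos + D, side="right")
    n_per = hi - np.arange(n) - 1
    csum = np.concatenate(([0], np.cumsum(n_per)))
    total = int(csum[-1])
    start = 0
    while start < n:
        stop = int(np.searchsorted(csum, csum[start] + block_pairs, side="left"))
        stop = max(start + 1, min(stop, n))
        i_counts = n_per[start:stop]
        i_idx = np.repeat(np.arange(start, stop), i_counts)
        if len(i_idx):
            j_idx = (np.arange(len(i_idx)) - (csum[start:stop] - csum[start])[i_idx - start]
                     + i_idx + 1)
            d = pos[j_idx] - pos[i_idx]
            w = cnt[i_idx].astype(np.float64) * cnt[j_idx]
            out += np.bincount(d, weights=w, minlength=D + 1).astype(np.int64)
        start = stop
    return out


def compute_phaseogram(track: DyadTrack, config: PhaseogramConfig) -> Phaseogram:
    """Build the phaseogram from a (filtered) dyad track.

    Per chromosome, all ordered dyad pairs within ``max_distance`` are
    counted with multiplicity; chromosomes with fewer than ``min_pairs``
    pairs are excluded from the average. Each included chromosome is
    normalised to unit mass over d = 1..D before the unweighted mean, so
    large chromosomes do not dominate.
    """
    D = config.max_distance
    counts: dict[str, np.ndarray] = {}
    freq: dict[str, np.ndarray] = {}
    n_pairs: dict[str, int] = {}
    included: list[str] = []
    for chrom, (pos, cnt) in track.data.items():
        c = _pair_counts(pos, cnt, D)
        counts[chrom] = c
        tot = int(c[1:].sum())
        n_pairs[chrom] = tot
        if tot >= config.min_pairs:
            freq[chrom] = c[1:] / tot
            included.append(chrom)
    if not included:
        raise InsufficientDataError(
            f"insufficient data: no chromosome reaches {config.min_pairs} dyad pairs")
    mean = np.mean(np.stack([freq[c] for c in included]), axis=0)
    return Phaseogram(max_distance=D, counts=counts, frequency=freq,
                      mean_frequency=mean, n_pairs=n_pairs, included=included)


def _smooth(y: np.ndarray, half_width: int) -> np.ndarray:
    """Centred moving average with edge-corrected normalisation."""
    if half_width <= 0:
        return y.astype(float)
    w = 2 * half_width + 1
    kernel = np.ones(w)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def detect_peaks(phaseogram: Phaseogram | np.ndarray,
                 config: PhaseogramConfig) -> np.ndarray:
    """Detect the oscillation peaks of the averaged phaseogram curve.

    The curve is smoothed, then local maxima inside the search range are
    collected (leftmost point of any plateau). Maxima whose topographic
    prominence falls below ``min_prominence_fraction`` of the strongest
    candidate's prominence are discarded — ripples riding on a smooth
    background are not oscillation peaks. Survivors are greedily accepted
    by decreasing height — leftmost first on exact ties — subject to the
    minimum separation, and returned left to right, capped at
    ``max_peaks``, as distances in bp.
    """
    curve = phaseogram.mean_frequency if isinstance(phaseogram, Phaseogram) else np.asarray(phaseogram, dtype=float)
    y = _smooth(curve, config.smoothing_half_width)
    lo, hi = config.resolved_search_range
    # distances are 1-based: curve index i corresponds to distance i+1
    cand: list[int] = []
    n = len(y)
    for i in range(n):
        d = i + 1
        if d < lo or d > hi:
            continue
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] > left and y[i] >= right:
            cand.append(i)
    if cand and config.min_prominence_fraction > 0:
        import warnings

        from scipy.signal import peak_prominences

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prom = peak_prominences(y, np.asarray(cand))[0]
        if prom.max() > 0:
            keep = prom >= config.min_prominence_fraction * prom.max()
            cand = [i for i, k in zip(cand, keep) if k]
    # greedy by height, leftmost on ties, enforcing separation
    cand.sort(key=lambda i: (-y[i], i))
    accepted: list[int] = []
    for i in cand:
        if all(abs(i - j) >= config.min_peak_separation for j in accepted):
            accepted.append(i)
    accepted.sort()
    peaks = np.array([i + 1 for i in accepted[:config.max_peaks]], dtype=np.int64)
    if len(peaks) < 3:
        raise TooFewPeaksError(f"too few peaks: found {len(peaks)}, need >= 3")
    return peaks


@dataclass
class NrlEstimate:
    """Result of the peak-position regression; ``nrl`` is the slope in bp."""

    peaks: np.ndarray           # detected peak positions, bp, k = 1..K
    nrl: float                  # regression slope (bp per peak index)
    intercept: float
    r_squared: float
    n_fragments: int | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def filter_harmonic_peaks(peaks: Sequence[int] | np.ndarray,
                          tolerance: float = 0.4) -> np.ndarray:
    """Keep the leading run of peaks consistent with one oscillation period.

    Oscillation peaks sit near k·NRL, so consecutive gaps should all be
    close to the first peak position. Walking left to right, a peak is
    accepted while its gap from the previous accepted peak lies within
    (1 ± tolerance) of the running mean gap (initialised to the first peak
    position); the remainder is truncated. This is the automatic stand-in
    for the manual peak curation interactive NRL tools rely on — it guards
    the regression against off-lattice maxima from non-spacing structure.
    """
    peaks = np.asarray(peaks)
    if tolerance <= 0 or len(peaks) < 2:
        return peaks
    accepted = [int(peaks[0])]
    gaps: list[int] = []
    expected = float(peaks[0])
    for p in peaks[1:]:
        gap = int(p) - accepted[-1]
        if (1 - tolerance) * expected <= gap <= (1 + tolerance) * expected:
            accepted.append(int(p))
            gaps.append(gap)
            expected = float(np.mean(gaps))
        else:
            break
    return np.array(accepted, dtype=np.int64)


def fit_nrl(peaks: Sequence[int] | np.ndarray) -> NrlEstimate:
    """Ordinary least squares of peak position on peak order (free intercept)."""
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 3:
        raise TooFewPeaksError(f"too few peaks for regression: {len(peaks)}")
    if not np.all(np.diff(peaks) > 0):
        raise ValueError("peak positions must be strictly increasing")
    k = np.arange(1, len(peaks) + 1, dtype=float)
    res = stats.linregress(k, peaks)
    return NrlEstimate(peaks=peaks.astype(np.int64), nrl=float(res.slope),
                       intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))


def restrict_to_regions(fragments: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Keep fragments whose dyad lies inside any region (half-open)."""
    if len(fragments) == 0:
        return fragments.copy()
    dyads = dyad_positions(fragments)
    keep = np.zeros(len(fragments), dtype=bool)
    frag_idx = fragments.groupby("chrom", sort=False).indices
    for chrom, ridx in regions.groupby("chrom", sort=False).indices.items():
        if chrom not in frag_idx:
            continue
        fi = frag_idx[chrom]
        d = dyads[fi]
        # merge candidate regions into sorted, possibly overlapping intervals
        starts = regions["start"].to_numpy()[ridx]
        ends = regions["end"].to_numpy()[ridx]
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], np.maximum.accumulate(ends[order])
        pos = np.searchsorted(starts, d, side="right") - 1
        ok = pos >= 0
        ok[ok] = d[ok] < ends[pos[ok]]
        keep[fi[ok]] = True
    return fragments.loc[keep].reset_index(drop=True)


def estimate_nrl(fragments: pd.DataFrame, config: PhaseogramConfig | None = None,
                 regions: pd.DataFrame | None = None,
                 size_band: tuple[int, int] | None = None) -> NrlEstimate:
    """Full NRL pipeline: filters -> dyad track -> phaseogram -> peaks -> fit.

    If *regions* is given, fragments are restricted beforehand to those
    whose dyad lies inside a region, so pair distances reflect intra-region
    spacing. The provenance dict records fragment counts retained at each
    stage together with the configuration used.
    """
    config = config or PhaseogramConfig()
    prov: dict = {"config": config, "n_input": int(len(fragments))}
    if size_band is not None:
        fragments = filter_by_size(fragments, size_band)
        prov["n_after_size_band"] = int(len(fragments))
    if regions is not None:
        fragments = restrict_to_regions(fragments, regions)
        prov["n_in_regions"] = int(len(fragments))
    fragments = cap_reads_per_chromosome(fragments, config.chromosome_read_cap,
                                         seed=config.seed)
    prov["n_after_cap"] = int(len(fragments))
    track = build_dyad_track(fragments)
    track = drop_stacked_positions(track, config.stacked_read_cutoff)
    prov["n_after_stack_filter"] = track.total
    if track.total < 2:
        raise InsufficientDataError("insufficient data: fewer than 2 dyads after filters")
    phase = compute_phaseogram(track, config)
    peaks = detect_peaks(phase, config)
    peaks = filter_harmonic_peaks(peaks, config.peak_spacing_tolerance)
    if len(peaks) < 3:
        raise TooFewPeaksError(
            f"too few peaks after harmonic filtering: {len(peaks)}")
    est = fit_nrl(peaks)
    est.n_fragments = prov["n_after_cap"]
    est.provenance = prov
    logger.info("estimate_nrl: NRL=%.2f bp from %d peaks (R^2=%.4f, %d fragments)",
                est.nrl, est.n_peaks, est.r_squared, est.n_fragments or -1)
    return est


# ---------------------------------------------------------------------------
# region presets used for per-region NRL
# ---------------------------------------------------------------------------

def tss_windows(tss: pd.DataFrame, genome: GenomeIndex | None = None,
                flank: int = 5000) -> pd.DataFrame:
    """Symmetric windows around transcription start sites.

    *tss* is a BED-like table with strand; the TSS is the interval start on
    the + strand and ``end - 1`` on the − strand. Windows are
    ``[tss - flank, tss + flank)``, clipped to chromosome bounds.
    """
    if "strand" not in tss.columns or (~tss["strand"].isin(["+", "-"])).any():
        raise ValueError("TSS windows require a +/− strand for every record")
    point = np.where(tss["strand"] == "+", tss["start"], tss["end"] - 1)
    out = tss.copy().reset_index(drop=True)
    out["start"] = np.maximum(0, point - flank)
    out["end"] = point + flank
    if genome is not None:
        out["end"] = np.minimum(out["end"], out["chrom"].map(genome.lengths))
    return out


def filter_gene_bodies(genes: pd.DataFrame, min_length: int = 1000,
                       max_length: int = 200_000) -> pd.DataFrame:
    """Gene bodies with min_length < length < max_length (strict bounds)."""
    length = genes["end"] - genes["start"]
    return genes.loc[(length > min_length) & (length < max_length)].reset_index(drop=True)


def pad_regions(regions: pd.DataFrame, pad: int = 1000,
                genome: GenomeIndex | None = None) -> pd.DataFrame:
    """Extend every region symmetrically by *pad* bp, clipped at chromosome ends."""
    out = regions.copy().reset_index(drop=True)
    out["start"] = np.maximum(0, out["start"] - pad)
    out["end"] = out["end"] + pad
    if genome is not None:
        out["end"] = np.minimum(out["end"], out["chrom"].map(genome.lengths))
    return out


def select_top_by_score(regions: pd.DataFrame, column: str = "score",
                        k: int = 3000, top: bool = True) -> pd.DataFrame:
    """Top-k (or bottom-k) regions by an external score column."""
    df = regions.sort_values(column, ascending=not top, kind="mergesort")
    return df.head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# paired-condition comparison
# ---------------------------------------------------------------------------

@dataclass
class NrlComparison:
    """Paired NRL comparison across patients (condition A minus condition B)."""

    patients: list
    nrl_a: np.ndarray
    nrl_b: np.ndarray
    differences: np.ndarray
    mean_difference: float
    t_statistic: float | None
    p_value: float | None            # two-sided
    p_value_one_sided: float | None  # H1: mean(A − B) > 0
    degenerate: bool = False


def compare_paired_nrl(table: pd.DataFrame) -> NrlComparison:
    """Paired-sample t test on per-patient NRL pairs.

    *table* needs columns ``patient``, ``nrl_a``, ``nrl_b``. Differences are
    ``nrl_a − nrl_b``; t = mean(d) / (sd(d)/√n) with n−1 degrees of freedom,
    two-sided p. With zero-variance differences the statistic is undefined
    and the comparison is reported as degenerate (no p emitted).
    """
    if len(table) < 2:
        raise ValueError("paired comparison requires at least 2 complete pairs")
    a = table["nrl_a"].to_numpy(dtype=float)
    b = table["nrl_b"].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("incomplete pairs in comparison table")
    d = a - b
    mean_d = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return NrlComparison(list(table["patient"]), a, b, d, mean_d,
                             None, None, None, degenerate=True)
    n = len(d)
    t = mean_d / (sd / math.sqrt(n))
    p_two = 2.0 * stats.t.sf(abs(t), df=n - 1)
    p_one = stats.t.sf(t, df=n - 1)
    return NrlComparison(list(table["patient"]), a, b, d, mean_d,
                         float(t), float(p_two), float(p_one))
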