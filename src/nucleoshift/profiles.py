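"""Aggregate occupancy and methylation profiles around feature sets.

Occupancy profiles accumulate per-bp fragment coverage over a symmetric
window around each feature centre (summed over features by default, with a
per-feature-average flag for the normalised-average presentation); ChIP
profiles are input-normalised by pointwise ratio; methylation profiles sum
CpG beta values by offset without further normalisation (arbitrary units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("nucleoshift")


@dataclass
class ProfileConfig:
    """Window, smoothing and normalisation settings for aggregate profiles.

    ``smoothing_window`` in bp is expanded to the next odd width so the
    moving average stays centred; ``per_million`` divides by (fragments in
    sample / 1e6); minus-strand features are mirrored when ``strand_aware``.
    """

    flank: int = 2000
    smoothing_window: int = 10
    per_million: bool = True
    strand_aware: bool = True
    per_feature_average: bool = False

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")

    @property
    def odd_smoothing_window(self) -> int:
        w = self.smoothing_window
        return w if w % 2 == 1 else w + 1


@dataclass
class OccupancyProfile:
    """Coverage values on the offset axis −flank..+flank (2·flank+1 points)."""

    flank: int
    values: np.ndarray
    n_features: int
    n_fragments: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


@dataclass
class MethylationProfile:
    """Summed beta per offset (arbitrary units), axis −flank..+flank."""

    flank: int
    values: np.ndarray
    n_features: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


def feature_centres(features: pd.DataFrame) -> np.ndarray:
    """Floor midpoint of each feature (same convention as fragment dyads)."""
    s = features["start"].to_numpy(np.int64)
    e = features["end"].to_numpy(np.int64)
    return s + (e - s) // 2


def _smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def aggregate_occupancy(fragments: pd.DataFrame, features: pd.DataFrame,
                        config: ProfileConfig | None = None) -> OccupancyProfile:
    """Per-bp fragment coverage accumulated over all features.

    For each feature the coverage of every overlapping fragment is added to
    the window [centre − flank, centre + flank] (inclusive), mirrored for
    minus-strand features when strand-aware. Depth normalisation divides by
    fragments-in-sample per million; smoothing is applied last.
    """
    config = config or ProfileConfig()
    if len(features) == 0:
        raise ValueError("aggregate_occupancy requires at least one feature")
    W = 2 * config.flank + 1
    diff = np.zeros(W + 1, dtype=float)
    centres = feature_centres(features)
    strands = (features["strand"].to_numpy() if "strand" in features.columns
               else np.full(len(features), "."))
    frag_idx = (fragments.groupby("chrom", sort=False).indices
                if len(fragments) else {})
    starts_all = fragments["start"].to_numpy(np.int64) if len(fragments) else None
    ends_all = fragments["end"].to_numpy(np.int64) if len(fragments) else None
    sorted_frags: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for chrom, idx in frag_idx.items():
        s, e = starts_all[idx], ends_all[idx]
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        sorted_frags[str(chrom)] = (s, e, int((e - s).max()))
    chroms = features["chrom"].to_numpy()
    for fi in range(len(features)):
        entry = sorted_frags.get(chroms[fi])
        if entry is None:
            continue
        s, e, max_len = entry
        c = centres[fi]
        win_lo, win_hi = c - config.flank, c + config.flank + 1  # half-open
        lo = np.searchsorted(s, win_lo - max_len + 1, side="left")
        hi = np.searchsorted(s, win_hi, side="left")
        if hi <= lo:
            continue
        a = np.clip(s[lo:hi] - win_lo, 0, W)
        b = np.clip(e[lo:hi] - win_lo, 0, W)
        keep = b > a
        a, b = a[keep], b[keep]
        if config.strand_aware and strands[fi] == "-":
            a, b = W - b, W - a
        np.add.at(diff, a, 1.0)
        np.add.at(diff, b, -1.0)
    values = np.cumsum(diff[:-1])
    if config.per_feature_average:
        values = values / len(features)
    if config.per_million and len(fragments):
        values = values / (len(fragments) / 1e6)
    values = _smooth_profile(values, config.odd_smoothing_window)
    return OccupancyProfile(flank=config.flank, values=values,
                            n_features=len(features), n_fragments=len(fragments))


def average_profiles(profiles: list[OccupancyProfile]) -> OccupancyProfile:
    """Pointwise arithmetic mean of profiles on identical axes.

    Masked (NaN) offsets propagate by available-case averaging: an offset
    missing in some profiles is averaged over the profiles that have it.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    flank = profiles[0].flank
    if any(p.flank != flank for p in profiles):
        raise ValueError("profiles have mismatched axes")
    stacked = np.stack([p.values for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
    return OccupancyProfile(flank=flank, values=mean,
                            n_features=sum(p.n_features for p in profiles),
                            n_fragments=sum(p.n_fragments for p in profiles))


def normalize_by_input(chip: OccupancyProfile, input_profile: OccupancyProfile,
                       min_input: float = 1e-12) -> OccupancyProfile:
    """Pointwise ChIP/Input ratio; offsets with input < min_input are masked
    (NaN), not zeroed."""
    if chip.flank != input_profile.flank:
        raise ValueError("profiles have mismatched axes")
    ratio = np.full_like(chip.values, np.nan, dtype=float)
    ok = input_profile.values >= min_input
    ratio[ok] = chip.values[ok] / input_profile.values[ok]
    return OccupancyProfile(flank=chip.flank, values=ratio,
                            n_features=chip.n_features, n_fragments=chip.n_fragments)


def aggregate_methylation(records: pd.DataFrame, features: pd.DataFrame,
                          config: ProfileConfig | None = None) -> MethylationProfile:
    """Sum CpG beta values by offset from feature centres.

    S[o] = Σ beta over all (CpG, feature) pairs at offset o; a CpG inside
    the flank of several features contributes to each. No normalisation —
    the profile is in arbitrary units, directly comparable only between
    feature sets over the same methylation track.
    """
    config = config or ProfileConfig()
    W = 2 * config.flank + 1
    values = np.zeros(W, dtype=float)
    if len(features) == 0:
        return MethylationProfile(flank=config.flank, values=values, n_features=0)
    centres = feature_centres(features)
    strands = (features["strand"].to_numpy() if "strand" in features.columns
               else np.full(len(features), "."))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if len(records):
        pos_all = records["position"].to_numpy(np.int64)
        beta_all = records["beta"].to_numpy(float)
        for chrom, idx in records.groupby("chrom", sort=False).indices.items():
            p, b = pos_all[idx], beta_all[idx]
            order = np.argsort(p, kind="mergesort")
            by_chrom[str(chrom)] = (p[order], b[order])
    chroms = features["chrom"].to_numpy()
    for fi in range(len(features)):
        entry = by_chrom.get(chroms[fi])
        if entry is None:
            continue
        pos, beta = entry
        c = centres[fi]
        lo = np.searchsorted(pos, c - config.flank, side="left")
        hi = np.searchsorted(pos, c + config.flank, side="right")
        if hi <= lo:
            continue
        off = pos[lo:hi] - c
        if config.strand_aware and strands[fi] == "-":
            off = -off
        np.add.at(values, off + config.flank, beta[lo:hi])
    return MethylationProfile(flank=config.flank, values=values,
                              n_features=len(features))
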