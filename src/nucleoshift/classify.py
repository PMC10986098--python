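"""Discrete nucleosome repositioning calls between two conditions.

Fragments of one patient are first reduced to *stable* nucleosomes —
positions reproduced almost exactly (99% overlap, i.e. about 1 bp of slack
on a ~150 bp fragment) in at least one other patient of the same condition.
Between the paired conditions A (reference, e.g. normal) and B (comparison,
e.g. tumour) the stable fragments are then labelled:

* **common** — stable in A with a ≥ 99% (non-reciprocal) match in stable B;
* **shifted** — stable in A with *no* reciprocal ≥ 80% match in stable B
  (the position moved by more than 20% of the fragment length);
* **gained** — stable in B with zero overlap against every stable A fragment;
* **lost** — stable in A with zero overlap against every stable B fragment.

Overlap-fraction semantics mirror ``bedtools intersect``: ``-u -f 0.99``
for stable/common, ``-f 0.80 -r -v`` for shifted. Fractional thresholds
are never rounded — the integer overlap is compared to the real-valued
threshold with ``>=``. Common and shifted are computed independently, so
fragments whose best match falls in the 80–99% zone carry neither label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragment_ops import filter_by_size

logger = logging.getLogger("nucleoshift")


@dataclass
class ClassificationConfig:
    """Overlap fractions and size band for repositioning calls."""

    f_stable: float = 0.99   # non-reciprocal, query fraction
    f_common: float = 0.99   # non-reciprocal
    f_shift: float = 0.80    # reciprocal, negated
    size_band: tuple[int, int] = (120, 180)

    def __post_init__(self) -> None:
        for f in (self.f_stable, self.f_common, self.f_shift):
            if not 0 < f <= 1:
                raise ValueError(f"overlap fraction {f} outside (0, 1]")


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp of two half-open intervals on the same chromosome."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


class IntervalIndex:
    """Sorted-start interval index over a fragment table.

    Candidate lookup uses the maximum interval length per chromosome to
    bound the scan window, so query cost is sublinear in set size for
    bounded-length fragments; results are identical to brute force.
    """

    def __init__(self, intervals: pd.DataFrame):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        if len(intervals) == 0:
            return
        starts_all = intervals["start"].to_numpy(np.int64)
        ends_all = intervals["end"].to_numpy(np.int64)
        for chrom, idx in intervals.groupby("chrom", sort=False).indices.items():
            s, e = starts_all[idx], ends_all[idx]
            order = np.argsort(s, kind="mergesort")
            s, e = s[order], e[order]
            self._chrom[str(chrom)] = (s, e, int((e - s).max()))

    def candidates(self, chrom: str, start: int, end: int
                   ) -> tuple[np.ndarray, np.ndarray]:
        """All intervals that could overlap [start, end) on chrom."""
        entry = self._chrom.get(chrom)
        if entry is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        s, e, max_len = entry
        lo = np.searchsorted(s, start - max_len + 1, side="left")
        hi = np.searchsorted(s, end, side="left")
        return s[lo:hi], e[lo:hi]


def _match_mask(query: pd.DataFrame, subjects: pd.DataFrame,
                f: float | None = None, reciprocal: bool = False,
                min_overlap_bp: int | None = None) -> np.ndarray:
    """Boolean mask: query intervals with a qualifying match in *subjects*.

    A match requires overlap >= f * len(query) (and >= f * len(subject)
    when *reciprocal*), or overlap >= *min_overlap_bp* when *f* is None.
    """
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subjects) == 0:
        return out
    index = IntervalIndex(subjects)
    chroms = query["chrom"].to_numpy()
    starts = query["start"].to_numpy(np.int64)
    ends = query["end"].to_numpy(np.int64)
    for i in range(len(query)):
        qs, qe = starts[i], ends[i]
        s, e = index.candidates(chroms[i], qs, qe)
        if len(s) == 0:
            continue
        ov = np.minimum(e, qe) - np.maximum(s, qs)
        if f is not None:
            ok = ov >= f * (qe - qs)
            if reciprocal:
                ok &= ov >= f * (e - s)
        else:
            ok = ov >= (1 if min_overlap_bp is None else min_overlap_bp)
        out[i] = bool(ok.any())
    return out


def has_match(fragment, subjects: pd.DataFrame, f: float,
              reciprocal: bool = False) -> bool:
    """True iff some subject overlaps *fragment* by >= f of its length
    (and >= f of the subject's length when *reciprocal*)."""
    q = pd.DataFrame({"chrom": [fragment.chrom], "start": [fragment.start],
                      "end": [fragment.end]})
    return bool(_match_mask(q, subjects, f=f, reciprocal=reciprocal)[0])


def call_stable(sample: pd.DataFrame, others: list[pd.DataFrame],
                config: ClassificationConfig | None = None) -> pd.DataFrame:
    """Fragments reproduced at >= f_stable (non-reciprocal) in >= 1 other patient."""
    config = config or ClassificationConfig()
    if not others:
        raise ValueError("stable calling requires at least one other patient set")
    mask = np.zeros(len(sample), dtype=bool)
    for other in others:
        mask |= _match_mask(sample, other, f=config.f_stable)
    return sample.loc[mask].reset_index(drop=True)


def call_common_shifted(stable_a: pd.DataFrame, stable_b: pd.DataFrame,
                        config: ClassificationConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Common (>= f_common match) and shifted (no reciprocal f_shift match)
    fragments of stable_a against stable_b; the two labels are independent."""
    config = config or ClassificationConfig()
    common_mask = _match_mask(stable_a, stable_b, f=config.f_common)
    shifted_mask = ~_match_mask(stable_a, stable_b, f=config.f_shift, reciprocal=True)
    return (stable_a.loc[common_mask].reset_index(drop=True),
            stable_a.loc[shifted_mask].reset_index(drop=True))


def call_gained_lost(stable_a: pd.DataFrame, stable_b: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gained: stable_b with zero overlap against all of stable_a;
    lost: stable_a with zero overlap against all of stable_b."""
    gained_mask = ~_match_mask(stable_b, stable_a, min_overlap_bp=1)
    lost_mask = ~_match_mask(stable_a, stable_b, min_overlap_bp=1)
    return (stable_b.loc[gained_mask].reset_index(drop=True),
            stable_a.loc[lost_mask].reset_index(drop=True))


@dataclass
class NucleosomeClassSet:
    """Labelled fragment sets for one patient's condition pair (A vs B)."""

    stable_a: pd.DataFrame
    stable_b: pd.DataFrame
    common: pd.DataFrame
    shifted: pd.DataFrame
    gained_b: pd.DataFrame
    lost_b: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name))
                for name in ("stable_a", "stable_b", "common", "shifted",
                             "gained_b", "lost_b")}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.counts.items()),
                            columns=["class", "n_fragments"])


def classify_pair(frags_a: pd.DataFrame, frags_b: pd.DataFrame,
                  others_a: list[pd.DataFrame], others_b: list[pd.DataFrame],
                  config: ClassificationConfig | None = None) -> NucleosomeClassSet:
    """Full pipeline: size-band filter, stable calling per condition, then
    common/shifted and gained/lost labelling.

    ``others_a`` / ``others_b`` are the same-condition fragment sets of the
    other patients, used only for stable calling.
    """
    config = config or ClassificationConfig()
    band = config.size_band
    frags_a = filter_by_size(frags_a, band)
    frags_b = filter_by_size(frags_b, band)
    others_a = [filter_by_size(o, band) for o in others_a]
    others_b = [filter_by_size(o, band) for o in others_b]
    stable_a = call_stable(frags_a, others_a, config)
    stable_b = call_stable(frags_b, others_b, config)
    common, shifted = call_common_shifted(stable_a, stable_b, config)
    gained, lost = call_gained_lost(stable_a, stable_b)
    result = NucleosomeClassSet(stable_a=stable_a, stable_b=stable_b,
                                common=common, shifted=shifted,
                                gained_b=gained, lost_b=lost)
    logger.info("classify_pair: %s", result.counts)
    return result
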