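"""Readers and writers for the external formats the pipeline touches.

All interval I/O is 0-based, half-open ``[start, end)`` — the BED convention.
No operation anywhere in the package interprets coordinates otherwise.

Fragments and regions are carried as :class:`pandas.DataFrame` objects
(columns ``chrom, start, end`` plus optional ``name, score, strand``), the
bulk container used throughout; the dataclasses below exist for record-level
validation and documentation of the schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nucleoshift")

FRAGMENT_COLUMNS = ["chrom", "start", "end"]
REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    """A BED line that cannot be interpreted (bad coordinates, end <= start)."""


class MethylationParseError(ValueError):
    """A methylation TSV row that cannot be interpreted or violates beta in [0,1]."""


@dataclass(frozen=True)
class GenomicFragment:
    """One MNase-protected DNA fragment: the atomic observation.

    ``length`` is ``end - start`` and ``dyad`` the floor midpoint
    ``start + length // 2`` (the inferred nucleosome centre).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def dyad(self) -> int:
        return self.start + self.length // 2


@dataclass(frozen=True)
class Region:
    """A named genomic interval (promoter, repeat, DMR, peak, gene body...)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."  # "+", "-" or "." (unstranded)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MethylationRecord:
    """Methylation level (beta in [0,1]) of a single CpG cytosine (0-based)."""

    chrom: str
    position: int
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta {self.beta} outside [0, 1]")


class GenomeIndex:
    """Ordered chromosome names and lengths, with optional sequence access.

    Sequence can come from an in-memory mapping (synthetic genomes) or a
    FASTA file via :mod:`pyfaidx`. ``sequence`` always returns uppercase
    bases for the half-open window ``[start, end)``.
    """

    def __init__(
        self,
        names: Sequence[str],
        lengths: Sequence[int],
        sequences: Mapping[str, str] | None = None,
        fasta_path: str | Path | None = None,
    ):
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")
        self.names: list[str] = list(names)
        self.lengths: dict[str, int] = dict(zip(self.names, (int(l) for l in lengths)))
        self._rank: dict[str, int] = {n: i for i, n in enumerate(self.names)}
        self._sequences = dict(sequences) if sequences is not None else None
        self._fasta = None
        if fasta_path is not None:
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(fasta_path))

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                         dtype={"chrom": str, "length": np.int64})
        return cls(df["chrom"].tolist(), df["length"].tolist())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        names = list(fa.keys())
        lengths = [len(fa[n]) for n in names]
        idx = cls(names, lengths)
        idx._fasta = fa
        return idx

    # -- queries ----------------------------------------------------------
    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def rank(self, chrom: str) -> int:
        return self._rank[chrom]

    @property
    def has_sequence(self) -> bool:
        return self._sequences is not None or self._fasta is not None

    def sequence(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.lengths:
            raise KeyError(chrom)
        start = max(0, int(start))
        end = min(self.lengths[chrom], int(end))
        if end <= start:
            return ""
        if self._sequences is not None:
            return self._sequences[chrom][start:end].upper()
        if self._fasta is not None:
            return str(self._fasta[chrom][start:end]).upper()
        raise RuntimeError("GenomeIndex has no sequence source")

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n in self.names:
                fh.write(f"{n}\t{self.lengths[n]}\n")


# ---------------------------------------------------------------------------
# fragment BED I/O
# ---------------------------------------------------------------------------

def _read_bed_table(path: str | Path, n_required: int = 3) -> pd.DataFrame:
    """Parse a BED file into a raw table, raising on malformed coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_required:
                raise BedParseError(f"{path}:{lineno}: expected >= {n_required} columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise BedParseError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end {end} <= start {start}")
            rows.append((fields[0], start, end, fields[3:]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "extra"])


def read_fragments(path: str | Path, genome: GenomeIndex) -> pd.DataFrame:
    """Read mapped fragment intervals from a BED3+ file.

    Columns beyond the first three are ignored. Records on chromosomes
    absent from *genome* (or running past the chromosome end) are dropped
    with a logged count; malformed lines are a hard error with the line
    number.
    """
    raw = _read_bed_table(path)
    if len(raw) == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    known = raw["chrom"].isin(genome.names)
    in_bounds = known.copy()
    lengths = raw.loc[known, "chrom"].map(genome.lengths)
    in_bounds.loc[known] = raw.loc[known, "end"].astype(np.int64) <= lengths.astype(np.int64)
    dropped = int((~(known & in_bounds)).sum())
    if dropped:
        logger.warning("read_fragments(%s): dropped %d record(s) on unknown or "
                       "out-of-bounds chromosomes", path, dropped)
    out = raw.loc[known & in_bounds, FRAGMENT_COLUMNS].reset_index(drop=True)
    return out.astype({"start": np.int64, "end": np.int64})


def write_fragments(fragments: pd.DataFrame, path: str | Path,
                    genome: GenomeIndex | None = None) -> None:
    """Write fragments as BED3, sorted by (genome chromosome order, start, end).

    Duplicates are preserved (multiset semantics); round-trips bit-exactly
    with :func:`read_fragments` on sorted input.
    """
    df = fragments[FRAGMENT_COLUMNS].copy()
    if genome is not None:
        df["_rank"] = df["chrom"].map({n: i for i, n in enumerate(genome.names)})
    else:
        df["_rank"] = df["chrom"]
    df = df.sort_values(["_rank", "start", "end"], kind="mergesort")
    with open(path, "w") as fh:
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 region set; name/score/strand default to '.', 0, '.'."""
    raw = _read_bed_table(path)
    name = [e[0] if len(e) > 0 else "." for e in raw["extra"]] if len(raw) else []
    score = [e[1] if len(e) > 1 else "0" for e in raw["extra"]] if len(raw) else []
    strand = [e[2] if len(e) > 2 else "." for e in raw["extra"]] if len(raw) else []
    df = pd.DataFrame({
        "chrom": raw["chrom"] if len(raw) else pd.Series(dtype=str),
        "start": pd.Series(raw["start"] if len(raw) else [], dtype=np.int64),
        "end": pd.Series(raw["end"] if len(raw) else [], dtype=np.int64),
        "name": pd.Series(name, dtype=str),
        "score": pd.to_numeric(pd.Series(score), errors="coerce").fillna(0.0),
        "strand": pd.Series(strand, dtype=str),
    })
    bad = ~df["strand"].isin(["+", "-", "."])
    if bad.any():
        df.loc[bad, "strand"] = "."
    return df


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    df = regions.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score}\t{row.strand}\n")


# ---------------------------------------------------------------------------
# methylation TSV
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV (chrom, 0-based CpG position, beta in [0,1]).

    Rows with beta outside [0,1] or unparseable are a hard error; order is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "position", "beta"],
                     dtype={"chrom": str})
    if len(df) == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "position": pd.Series(dtype=np.int64),
                             "beta": pd.Series(dtype=float)})
    beta = pd.to_numeric(df["beta"], errors="coerce")
    if beta.isna().any():
        bad = int(beta.isna().idxmax()) + 1
        raise MethylationParseError(f"{path}: row {bad}: beta not a number")
    if ((beta < 0) | (beta > 1)).any():
        bad = int(((beta < 0) | (beta > 1)).idxmax()) + 1
        raise MethylationParseError(f"{path}: row {bad}: beta outside [0, 1]")
    df["position"] = df["position"].astype(np.int64)
    df["beta"] = beta.astype(float)
    return df


def write_methylation(records: pd.DataFrame, path: str | Path) -> None:
    records[["chrom", "position", "beta"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g")
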