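"""Synthetic cohort generator: the test substrate for the whole pipeline.

The generator emulates the structure of paired tumour/normal MNase-derived
fragment data: phased nucleosome arrays with condition-specific repeat
length (tumour arrays a few bp shorter), a fragment-length mixture with
subnucleosomal, core, chromatosome and dinucleosome components, per-patient
reproducible "stable" positions, condition-specific gained / lost / shifted
events, and CpG methylation that is high at retained and low at shifted
nucleosomes. Ground truth (maps, repeat lengths, event lists) is kept for
parameter-recovery tests.

Fragment boundaries are drawn from a small per-locus pool of candidate
cut-site pairs that is shared across patients and conditions, emulating the
sequence-dependent cut-site preference of micrococcal nuclease. This is
what makes cross-patient reproduction of fragment coordinates at ~1 bp
precision — the basis of stable-nucleosome calling — a common event, as it
is in deep real data; with fully independent per-fragment boundaries such
coincidences would be vanishingly rare at any realistic coverage.

All outputs are a pure function of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeIndex, write_fragments, write_methylation

logger = logging.getLogger("nucleoshift")

# fixed substream tags so stages are independently reproducible
_S_GENOME, _S_MAPS, _S_POOLS, _S_PATIENTS, _S_FRAGMENTS, _S_METH = range(6)

KIND_CONSERVED, KIND_LOST, KIND_SHIFTED, KIND_GAINED = ("conserved", "lost",
                                                        "shifted", "gained")


def _rng(seed: int, stage: int, extra: Sequence[int] = ()) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage), *map(int, extra)])


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (fixed tie rule for reproducibility)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass
class SyntheticConfig:
    """Study conditions emulated by the generator.

    Defaults mirror the data structure the analysis assumes: normal repeat
    length 193 bp versus tumour 186 bp (a 7 bp shortening, in the reported
    5–10 bp range), a fragment mixture of subnucleosomal (130 bp), core
    particle (147 bp), chromatosome (168 bp) and ~20% dinucleosome (320 bp)
    components, 3 patients with 0.9 cross-patient position reproducibility,
    and 5% gained / lost / shifted events each. Arrays are separated by
    long nucleosome-depleted gaps (default 2500 +/- 300 bp, i.e. wider than
    the 2000 bp phaseogram window) so inter-array dyad distances do not
    contaminate the spacing signal.
    """

    seed: int = 0
    chromosomes: tuple[tuple[str, int, float], ...] = (
        ("chr1", 1_500_000, 0.38), ("chr2", 1_500_000, 0.44))
    array_length: int = 1100
    inter_array_gap: int = 2500
    gap_jitter: int = 300                # gaps vary uniformly by +/- this
    n_arrays: int | None = None          # per chromosome; None = fill
    nrl_normal: float = 193.0
    nrl_delta: float = 7.0               # tumour NRL = normal − delta
    jitter_sd: float = 10.0              # positional jitter of map dyads, bp
    coverage: float = 20.0               # mean fragments per nucleosome
    fragment_mixture: tuple[tuple[float, float, float], ...] = (
        (130.0, 10.0, 0.15), (147.0, 7.0, 0.45),
        (168.0, 8.0, 0.20), (320.0, 20.0, 0.20))
    gained_fraction: float = 0.05
    lost_fraction: float = 0.05
    shifted_fraction: float = 0.05
    shift_displacement: int = 60         # >= 25% of a core fragment length
    n_patients: int = 3
    reproducibility: float = 0.9
    pool_size: int = 6                   # candidate cut-site pairs per locus
    centre_jitter_sd: float = 5.0        # fragment centre offsets within a pool
    min_fragment_length: int = 50
    meth_beta_high: float = 0.8
    meth_beta_low: float = 0.2
    meth_beta_sd: float = 0.1
    meth_window: int = 74                # bp around a dyad assigned its class
    cpg_rate: float | None = None        # target CpGs per bp; None = all CG sites

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.fragment_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w}, expected 1")
        if self.nrl_delta < 0:
            raise ValueError("nrl_delta must be >= 0")
        for f in (self.gained_fraction, self.lost_fraction, self.shifted_fraction,
                  self.reproducibility):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} outside [0, 1]")
        for L in (self.nrl_normal, self.nrl_tumour):
            if L <= 2 * self.jitter_sd:
                raise ValueError(f"repeat length {L} <= 2*jitter sd: arrays "
                                 "would be unordered")

    @property
    def nrl_tumour(self) -> float:
        return self.nrl_normal - self.nrl_delta

    @property
    def sample_names(self) -> list[tuple[int, str]]:
        return [(p, cond) for p in range(1, self.n_patients + 1)
                for cond in ("normal", "tumour")]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort.

    ``loci`` has one row per nucleosome locus (chrom, array, index, kind,
    pos_normal, pos_tumour; −1 marks absence in a condition); ``events``
    restricts it to gained/lost/shifted rows. Per-patient dyad positions
    aligned to ``loci`` live in ``patient_positions[(patient, condition)]``.
    """

    config: SyntheticConfig
    loci: pd.DataFrame
    nrl: dict[str, float]
    patient_positions: dict[tuple[int, str], np.ndarray]
    pool_lengths: np.ndarray = field(repr=False, default=None)   # (n_loci, pool)
    pool_offsets: np.ndarray = field(repr=False, default=None)

    @property
    def events(self) -> pd.DataFrame:
        return self.loci.loc[self.loci["kind"] != KIND_CONSERVED].reset_index(drop=True)

    def dyads(self, condition: str, kinds: Sequence[str] | None = None
              ) -> pd.DataFrame:
        """Base-map dyads of one condition as a (chrom, position) table."""
        col = f"pos_{condition}"
        sel = self.loci.loc[self.loci[col] >= 0]
        if kinds is not None:
            sel = sel.loc[sel["kind"].isin(kinds)]
        return (sel[["chrom", col]].rename(columns={col: "position"})
                .sort_values(["chrom", "position"], kind="mergesort")
                .reset_index(drop=True))


def generate_genome(config: SyntheticConfig,
                    fasta_path: str | Path | None = None) -> GenomeIndex:
    """I.i.d. random genome with per-chromosome GC probability.

    Bases are drawn with P(G) = P(C) = gc/2 and P(A) = P(T) = (1−gc)/2;
    optionally written as FASTA (60-column lines).
    """
    sequences: dict[str, str] = {}
    names, lengths = [], []
    for ci, (name, length, gc) in enumerate(config.chromosomes):
        rng = _rng(config.seed, _S_GENOME, (ci,))
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                           p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences[name] = bases.tobytes().decode("ascii")
        names.append(name)
        lengths.append(length)
    genome = GenomeIndex(names, lengths, sequences=sequences)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for name in names:
                fh.write(f">{name}\n")
                seq = sequences[name]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    return genome


def generate_nucleosome_maps(config: SyntheticConfig,
                             genome: GenomeIndex | None = None) -> SyntheticTruth:
    """Build base nucleosome maps, events and per-patient copies.

    Normal arrays place dyads at anchor + k·L_normal + N(0, jitter²); the
    tumour map reuses each array's jittered normal positions with a
    centre-anchored re-spacing at L_tumour (position k moves by
    −Δ·(k − (n−1)/2)), so the array midpoint is preserved and the
    per-locus correspondence that defines events stays exact. Lost loci are
    removed from the tumour map, shifted loci displaced by
    ±shift_displacement, and gained loci planted at inter-array gap centres
    (tumour only). Patient maps copy each base position with probability
    ``reproducibility`` and otherwise jitter it by up to ±3 bp.
    """
    if genome is None:
        genome = GenomeIndex([c[0] for c in config.chromosomes],
                             [c[1] for c in config.chromosomes])
    L_n, L_t = config.nrl_normal, config.nrl_tumour
    rows = []  # chrom, array, k, pos_normal
    gap_centres = []  # (chrom, centre)
    for ci, name in enumerate(genome.names):
        rng = _rng(config.seed, _S_MAPS, (ci,))
        chrom_len = genome.length(name)
        n_k = max(1, len([k for k in range(int(np.ceil(config.array_length / L_n)) + 1)
                          if k * L_n < config.array_length]))
        cursor, ai = 0, 0
        # gap lengths are jittered so cross-array dyad distances smear into
        # a broad background instead of forming a second peak family
        while config.n_arrays is None or ai < config.n_arrays:
            gap = config.inter_array_gap
            if config.gap_jitter:
                gap += int(rng.integers(-config.gap_jitter, config.gap_jitter + 1))
            gap = max(gap, 2 * config.meth_window + 2)
            p0 = cursor + gap
            if p0 + config.array_length > chrom_len:
                break
            gap_centres.append((name, cursor + gap // 2))
            offs = np.arange(n_k) * L_n + rng.normal(0.0, config.jitter_sd, n_k)
            pos = p0 + _round_half_away(offs)
            pos = pos[(pos >= 0) & (pos < min(p0 + config.array_length, chrom_len))]
            for k, p in enumerate(pos):
                rows.append((name, ai, k, int(p)))
            cursor = p0 + config.array_length
            ai += 1
    loci = pd.DataFrame(rows, columns=["chrom", "array", "k", "pos_normal"])
    n_loci = len(loci)

    # tumour re-spacing, centre-anchored per array
    pos_tumour = np.full(n_loci, -1, dtype=np.int64)
    for (chrom, ai), idx in loci.groupby(["chrom", "array"], sort=False).indices.items():
        ks = loci["k"].to_numpy()[idx].astype(float)
        centre_k = (ks.max() + ks.min()) / 2.0
        drift = _round_half_away(-(L_n - L_t) * (ks - centre_k))
        pos_tumour[idx] = loci["pos_normal"].to_numpy()[idx] + drift

    # event assignment over array loci
    rng_ev = _rng(config.seed, _S_MAPS, (10_000,))
    p_cons = 1.0 - config.lost_fraction - config.shifted_fraction
    kind = rng_ev.choice([KIND_CONSERVED, KIND_LOST, KIND_SHIFTED], size=n_loci,
                         p=[p_cons, config.lost_fraction, config.shifted_fraction])
    loci["kind"] = kind
    loci["pos_tumour"] = pos_tumour
    lost = loci["kind"] == KIND_LOST
    loci.loc[lost, "pos_tumour"] = -1
    shifted = (loci["kind"] == KIND_SHIFTED).to_numpy()
    signs = rng_ev.choice([-1, 1], size=int(shifted.sum()))
    loci.loc[shifted, "pos_tumour"] = (loci.loc[shifted, "pos_tumour"]
                                       + signs * config.shift_displacement)

    # gained loci at gap centres (tumour only)
    n_gained = int(round(config.gained_fraction * n_loci))
    n_gained = min(n_gained, len(gap_centres))
    if n_gained:
        chosen = rng_ev.choice(len(gap_centres), size=n_gained, replace=False)
        gained_rows = [(gap_centres[i][0], -1, -1, -1, KIND_GAINED,
                        int(gap_centres[i][1])) for i in sorted(chosen)]
        loci = pd.concat([loci, pd.DataFrame(
            gained_rows, columns=["chrom", "array", "k", "pos_normal", "kind",
                                  "pos_tumour"])], ignore_index=True)
    loci = loci[["chrom", "array", "k", "kind", "pos_normal", "pos_tumour"]]
    loci = loci.astype({"pos_normal": np.int64, "pos_tumour": np.int64})
    n_loci = len(loci)

    # shared per-locus fragment-boundary pools (mono components only)
    mono = [c for c in config.fragment_mixture if c[0] < 250]
    w = np.array([c[2] for c in mono]); w = w / w.sum()
    rng_pool = _rng(config.seed, _S_POOLS)
    comp = rng_pool.choice(len(mono), size=(n_loci, config.pool_size), p=w)
    means = np.array([c[0] for c in mono])[comp]
    sds = np.array([c[1] for c in mono])[comp]
    pool_lengths = _round_half_away(rng_pool.normal(means, sds))
    pool_lengths = np.maximum(pool_lengths, config.min_fragment_length)
    pool_offsets = _round_half_away(
        rng_pool.normal(0.0, config.centre_jitter_sd, size=(n_loci, config.pool_size)))

    # per-patient maps
    patient_positions: dict[tuple[int, str], np.ndarray] = {}
    for p in range(1, config.n_patients + 1):
        for cond in ("normal", "tumour"):
            rng_p = _rng(config.seed, _S_PATIENTS, (p, 0 if cond == "normal" else 1))
            base = loci[f"pos_{cond}"].to_numpy().copy()
            present = base >= 0
            shared = rng_p.random(n_loci) < config.reproducibility
            jit = rng_p.choice([-3, -2, -1, 1, 2, 3], size=n_loci)
            base[present & ~shared] += jit[present & ~shared]
            patient_positions[(p, cond)] = base
    truth = SyntheticTruth(config=config, loci=loci,
                           nrl={"normal": L_n, "tumour": L_t},
                           patient_positions=patient_positions,
                           pool_lengths=pool_lengths, pool_offsets=pool_offsets)
    logger.info("generate_nucleosome_maps: %d loci (%s)", n_loci,
                loci["kind"].value_counts().to_dict())
    return truth


def generate_fragments(truth: SyntheticTruth,
                       config: SyntheticConfig | None = None
                       ) -> dict[tuple[int, str], pd.DataFrame]:
    """Draw per-sample fragments from the truth maps.

    Each present locus yields Poisson(coverage) fragments. A fragment is a
    dinucleosome with the mixture's dinucleosome weight — spanning the
    locus and its right neighbour (falling back to a mono draw when the
    locus is isolated) — and otherwise a uniformly chosen item of the
    locus's shared boundary pool, centred on the patient's dyad.
    """
    config = config or truth.config
    chrom_len = {name: length for name, length, _ in config.chromosomes}
    loci = truth.loci
    n_loci = len(loci)
    chrom_arr = loci["chrom"].to_numpy()
    array_arr = loci["array"].to_numpy()
    w_di = sum(c[2] for c in config.fragment_mixture if c[0] >= 250)
    di_mean, di_sd = next(((c[0], c[1]) for c in config.fragment_mixture
                           if c[0] >= 250), (320.0, 20.0))
    # right neighbour within the same chromosome+array (−1 if none)
    neighbour = np.full(n_loci, -1, dtype=np.int64)
    nxt = np.arange(1, n_loci)
    ok = (chrom_arr[:-1] == chrom_arr[nxt]) & (array_arr[:-1] == array_arr[nxt]) \
        & (array_arr[:-1] >= 0)
    neighbour[:-1][ok] = nxt[ok]

    out: dict[tuple[int, str], pd.DataFrame] = {}
    for p, cond in config.sample_names:
        rng = _rng(config.seed, _S_FRAGMENTS, (p, 0 if cond == "normal" else 1))
        pos = truth.patient_positions[(p, cond)]
        present = np.flatnonzero(pos >= 0)
        counts = rng.poisson(config.coverage, size=len(present))
        rep = np.repeat(present, counts)
        n_frag = len(rep)
        is_di = rng.random(n_frag) < w_di
        pick = rng.integers(0, config.pool_size, size=n_frag)
        centre = pos[rep] + truth.pool_offsets[rep, pick]
        length = truth.pool_lengths[rep, pick].copy()
        # dinucleosome fragments span the locus and its neighbour
        nb = neighbour[rep]
        di_ok = is_di & (nb >= 0)
        di_ok[di_ok] &= pos[nb[di_ok]] >= 0
        if di_ok.any():
            mid = (pos[rep[di_ok]] + pos[nb[di_ok]]) // 2
            centre[di_ok] = mid + _round_half_away(
                rng.normal(0.0, config.centre_jitter_sd, int(di_ok.sum())))
            length[di_ok] = np.maximum(
                _round_half_away(rng.normal(di_mean, di_sd, int(di_ok.sum()))),
                config.min_fragment_length)
        start = centre - length // 2
        end = start + length
        lim = np.array([chrom_len[c] for c in chrom_arr[rep]])
        keep = (start >= 0) & (end <= lim)
        df = pd.DataFrame({"chrom": chrom_arr[rep][keep],
                           "start": start[keep].astype(np.int64),
                           "end": end[keep].astype(np.int64)})
        df = df.sort_values(["chrom", "start", "end"],
                            kind="mergesort").reset_index(drop=True)
        out[(p, cond)] = df
    return out


def generate_methylation(truth: SyntheticTruth, genome: GenomeIndex,
                         config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Per-CpG beta values tied to the truth classes.

    CpG sites are CG dinucleotides of the generated genome (position of the
    C). A CpG within ``meth_window`` bp of a conserved normal-map dyad gets
    beta ~ N(beta_high, sd); within the window of a shifted locus's normal
    dyad, N(beta_low, sd); otherwise uniform [0, 1]. Betas are clipped to
    [0, 1]. Returns chrom, position, beta, class.
    """
    config = config or truth.config
    rng = _rng(config.seed, _S_METH)
    cons = truth.dyads("normal", kinds=[KIND_CONSERVED])
    shif = truth.loci.loc[(truth.loci["kind"] == KIND_SHIFTED)
                          & (truth.loci["pos_normal"] >= 0),
                          ["chrom", "pos_normal"]].rename(
                              columns={"pos_normal": "position"})
    frames = []
    for name in genome.names:
        seq = np.frombuffer(genome.sequence(name, 0, genome.length(name))
                            .encode("ascii"), dtype=np.uint8)
        is_cg = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
        pos = np.flatnonzero(is_cg).astype(np.int64)
        if config.cpg_rate is not None and len(pos):
            density = len(pos) / genome.length(name)
            keep_p = min(1.0, config.cpg_rate / density)
            pos = pos[rng.random(len(pos)) < keep_p]
        if len(pos) == 0:
            continue

        def _near(dyads_df: pd.DataFrame) -> np.ndarray:
            d = dyads_df.loc[dyads_df["chrom"] == name, "position"].to_numpy()
            if len(d) == 0:
                return np.zeros(len(pos), dtype=bool)
            d = np.sort(d)
            i = np.clip(np.searchsorted(d, pos), 0, len(d) - 1)
            dist = np.abs(d[i] - pos)
            dist = np.minimum(dist, np.abs(d[np.maximum(i - 1, 0)] - pos))
            return dist <= config.meth_window

        near_cons = _near(cons)
        near_shift = _near(shif) & ~near_cons
        beta = rng.uniform(0.0, 1.0, size=len(pos))
        beta[near_cons] = rng.normal(config.meth_beta_high, config.meth_beta_sd,
                                     int(near_cons.sum()))
        beta[near_shift] = rng.normal(config.meth_beta_low, config.meth_beta_sd,
                                      int(near_shift.sum()))
        cls = np.full(len(pos), "background", dtype=object)
        cls[near_cons] = "conserved"
        cls[near_shift] = "shifted"
        frames.append(pd.DataFrame({"chrom": name, "position": pos,
                                    "beta": np.clip(beta, 0.0, 1.0),
                                    "class": cls}))
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "position": pd.Series(dtype=np.int64),
                             "beta": pd.Series(dtype=float),
                             "class": pd.Series(dtype=str)})
    return pd.concat(frames, ignore_index=True)


@dataclass
class Cohort:
    """In-memory cohort plus (optionally) the files written for it."""

    config: SyntheticConfig
    genome: GenomeIndex
    truth: SyntheticTruth
    fragments: dict[tuple[int, str], pd.DataFrame]
    methylation: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def generate_cohort(config: SyntheticConfig,
                    out_dir: str | Path | None = None,
                    with_sequence: bool = True) -> Cohort:
    """Generate the full cohort; write the directory tree when *out_dir* given.

    The tree holds the FASTA genome, chrom.sizes, one fragment BED per
    patient and condition, the methylation TSV, truth tables, and a
    manifest listing every artefact with its checksum.
    """
    if with_sequence:
        genome = generate_genome(config)
    else:
        genome = GenomeIndex([c[0] for c in config.chromosomes],
                             [c[1] for c in config.chromosomes])
    truth = generate_nucleosome_maps(config, genome)
    fragments = generate_fragments(truth, config)
    methylation = (generate_methylation(truth, genome, config)
                   if with_sequence else pd.DataFrame(
                       columns=["chrom", "position", "beta", "class"]))
    cohort = Cohort(config=config, genome=genome, truth=truth,
                    fragments=fragments, methylation=methylation)
    if out_dir is None:
        return cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if with_sequence:
        paths["genome.fa"] = out / "genome.fa"
        generate_genome(config, fasta_path=paths["genome.fa"])
    paths["chrom.sizes"] = out / "chrom.sizes"
    genome.write_chrom_sizes(paths["chrom.sizes"])
    for (p, cond), df in fragments.items():
        key = f"patient{p}_{cond}.bed"
        paths[key] = out / key
        write_fragments(df, paths[key], genome)
    paths["methylation.tsv"] = out / "methylation.tsv"
    write_methylation(methylation, paths["methylation.tsv"])
    paths["truth_loci.tsv"] = out / "truth_loci.tsv"
    truth.loci.to_csv(paths["truth_loci.tsv"], sep="\t", index=False)
    paths["truth_nrl.tsv"] = out / "truth_nrl.tsv"
    pd.DataFrame([{"condition": c, "nrl": v} for c, v in truth.nrl.items()]
                 ).to_csv(paths["truth_nrl.tsv"], sep="\t", index=False)
    manifest = pd.DataFrame(
        [{"file": name, "sha256": _sha256(path), "seed": config.seed}
         for name, path in sorted(paths.items())])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    paths["manifest.tsv"] = out / "manifest.tsv"
    cohort.paths = paths
    return cohort
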