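"""End-to-end driver: simulate a cohort, run every analysis stage, report.

The run mirrors a paired tumour/normal study design: per-sample fragment
size fractionation, genome-wide NRL estimation, the paired NRL comparison,
per-patient repositioning classification scored against the generator
truth, aggregate occupancy/methylation profiles, and enrichment of gained
nucleosomes in the planted gained loci.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationConfig, NucleosomeClassSet, classify_pair
from .enrichment import fisher_enrichment
from .fragment_ops import DEFAULT_SIZE_BINS, dyad_positions, filter_by_size
from .nrl import PhaseogramConfig, compare_paired_nrl, estimate_nrl
from .profiles import ProfileConfig, aggregate_methylation, aggregate_occupancy
from .synthetic import (KIND_CONSERVED, KIND_GAINED, KIND_LOST, KIND_SHIFTED,
                        Cohort, SyntheticConfig, SyntheticTruth, generate_cohort)

logger = logging.getLogger("nucleoshift")


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("nucleoshift")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, level.upper()))


@dataclass
class PipelineConfig:
    """Resolved configuration of an end-to-end run; unknown keys are rejected."""

    seed: int = 0
    log_level: str = "INFO"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    phaseogram: PhaseogramConfig = field(default_factory=PhaseogramConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    enrichment_shuffles: int = 10
    size_band: tuple[int, int] = (120, 180)
    max_profile_features: int = 2000

    def __post_init__(self) -> None:
        # one global seed flows into every stage's named substream
        self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)
        self.phaseogram = dataclasses.replace(self.phaseogram, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub_cls in (("synthetic", SyntheticConfig),
                             ("phaseogram", PhaseogramConfig),
                             ("classification", ClassificationConfig),
                             ("profile", ProfileConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(tuple(x) if isinstance(x, list) else x
                                       for x in v)
                kwargs[key] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "size_band" in kwargs and isinstance(kwargs["size_band"], list):
            kwargs["size_band"] = tuple(kwargs["size_band"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# truth-based scoring of classification output
# ---------------------------------------------------------------------------

def _near_any(positions: np.ndarray, targets: np.ndarray, window: int) -> np.ndarray:
    """Mask of positions within *window* bp of any (sorted) target."""
    if len(targets) == 0:
        return np.zeros(len(positions), dtype=bool)
    t = np.sort(targets)
    i = np.clip(np.searchsorted(t, positions), 0, len(t) - 1)
    dist = np.abs(t[i] - positions)
    dist = np.minimum(dist, np.abs(t[np.maximum(i - 1, 0)] - positions))
    return dist <= window


def _locus_hits(labelled: pd.DataFrame, truth_loci: pd.DataFrame,
                pos_col: str, window: int) -> tuple[float, float]:
    """(event recall, fragment-level FDR) of one label against truth loci.

    An event is recovered when at least one correctly-labelled fragment
    dyad falls within *window* bp of its dyad; a labelled fragment is a
    false discovery when its dyad is near no truth locus of that kind.
    """
    if len(truth_loci) == 0:
        return float("nan"), float("nan")
    recovered = 0
    dyads_by_chrom: dict[str, np.ndarray] = {}
    if len(labelled):
        d = dyad_positions(labelled)
        for chrom, idx in labelled.groupby("chrom", sort=False).indices.items():
            dyads_by_chrom[str(chrom)] = np.sort(d[idx])
    for chrom, grp in truth_loci.groupby("chrom", sort=False):
        dy = dyads_by_chrom.get(str(chrom), np.empty(0, dtype=np.int64))
        targets = grp[pos_col].to_numpy()
        recovered += int(_near_any(targets, dy, window).sum())
    recall = recovered / len(truth_loci)
    if len(labelled) == 0:
        return recall, float("nan")
    false = 0
    d = dyad_positions(labelled)
    for chrom, idx in labelled.groupby("chrom", sort=False).indices.items():
        targets = truth_loci.loc[truth_loci["chrom"] == chrom, pos_col].to_numpy()
        false += int((~_near_any(d[idx], targets, window)).sum())
    return recall, false / len(labelled)


def evaluate_classification(truth: SyntheticTruth, result: NucleosomeClassSet,
                            window: int = 74) -> dict[str, float]:
    """Recall of planted gained/lost/shifted events and gained/lost FDR."""
    loci = truth.loci
    gained = loci.loc[loci["kind"] == KIND_GAINED]
    lost = loci.loc[loci["kind"] == KIND_LOST]
    shifted = loci.loc[loci["kind"] == KIND_SHIFTED]
    g_rec, g_fdr = _locus_hits(result.gained_b, gained, "pos_tumour", window)
    l_rec, l_fdr = _locus_hits(result.lost_b, lost, "pos_normal", window)
    s_rec, _ = _locus_hits(result.shifted, shifted, "pos_normal", window)
    return {"gained_recall": g_rec, "gained_fdr": g_fdr,
            "lost_recall": l_rec, "lost_fdr": l_fdr,
            "shifted_recall": s_rec}


# ---------------------------------------------------------------------------
# the end-to-end run
# ---------------------------------------------------------------------------

def run_end_to_end(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write a report directory.

    Returns the report as a dict (also written as report.tsv/report.md with
    the resolved configuration alongside).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    report: dict = {}

    logger.info("stage simulate")
    cohort = generate_cohort(config.synthetic, out_dir=out / "cohort")
    truth = cohort.truth

    logger.info("stage size fractionation")
    size_rows = []
    for (p, cond), df in cohort.fragments.items():
        lengths = (df["end"] - df["start"]).to_numpy()
        row = {"patient": p, "condition": cond, "n_fragments": len(df)}
        for low, high in DEFAULT_SIZE_BINS:
            row[f"n_{low}_{high}"] = int(((lengths >= low) & (lengths < high)).sum())
        size_rows.append(row)
    pd.DataFrame(size_rows).to_csv(out / "size_fractions.tsv", sep="\t", index=False)

    logger.info("stage NRL per sample")
    nrl_rows = []
    for (p, cond), df in cohort.fragments.items():
        est = estimate_nrl(df, config.phaseogram, size_band=config.size_band)
        nrl_rows.append({"patient": p, "condition": cond, "nrl": est.nrl,
                         "intercept": est.intercept, "r_squared": est.r_squared,
                         "n_peaks": est.n_peaks, "n_fragments": est.n_fragments,
                         "true_nrl": truth.nrl[cond],
                         "delta_vs_truth": est.nrl - truth.nrl[cond]})
    nrl_df = pd.DataFrame(nrl_rows)
    nrl_df.to_csv(out / "nrl_estimates.tsv", sep="\t", index=False)
    report["nrl_estimates"] = nrl_df

    logger.info("stage paired comparison")
    wide = nrl_df.pivot(index="patient", columns="condition", values="nrl")
    pairs = pd.DataFrame({"patient": wide.index,
                          "nrl_a": wide["normal"].to_numpy(),
                          "nrl_b": wide["tumour"].to_numpy()})
    comp = compare_paired_nrl(pairs)
    comp_df = pd.DataFrame([{"mean_difference_bp": comp.mean_difference,
                             "t_statistic": comp.t_statistic,
                             "p_two_sided": comp.p_value,
                             "p_one_sided": comp.p_value_one_sided,
                             "n_pairs": len(pairs),
                             "true_difference_bp": config.synthetic.nrl_delta}])
    comp_df.to_csv(out / "paired_nrl.tsv", sep="\t", index=False)
    report["paired_nrl"] = comp_df

    logger.info("stage classification")
    class_rows = []
    for p in range(1, config.synthetic.n_patients + 1):
        others_a = [cohort.fragments[(q, "normal")]
                    for q in range(1, config.synthetic.n_patients + 1) if q != p]
        others_b = [cohort.fragments[(q, "tumour")]
                    for q in range(1, config.synthetic.n_patients + 1) if q != p]
        result = classify_pair(cohort.fragments[(p, "normal")],
                               cohort.fragments[(p, "tumour")],
                               others_a, others_b, config.classification)
        scores = evaluate_classification(truth, result)
        class_rows.append({"patient": p, **result.counts, **scores})
        if p == 1:
            report["classification_p1"] = result
    class_df = pd.DataFrame(class_rows)
    class_df.to_csv(out / "classification.tsv", sep="\t", index=False)
    report["classification"] = class_df

    logger.info("stage profiles")
    prof_cfg = config.profile
    cons = truth.dyads("normal", kinds=[KIND_CONSERVED]).head(config.max_profile_features)
    cons_feat = pd.DataFrame({"chrom": cons["chrom"],
                              "start": cons["position"],
                              "end": cons["position"] + 1})
    occ = aggregate_occupancy(cohort.fragments[(1, "normal")], cons_feat, prof_cfg)
    occ.to_frame().to_csv(out / "occupancy_conserved.tsv", sep="\t", index=False)
    report["occupancy_central_mean"] = float(
        np.nanmean(occ.values[occ.flank - 50: occ.flank + 51]))
    shif = truth.loci.loc[(truth.loci["kind"] == KIND_SHIFTED)
                          & (truth.loci["pos_normal"] >= 0)]
    shif_feat = pd.DataFrame({"chrom": shif["chrom"],
                              "start": shif["pos_normal"],
                              "end": shif["pos_normal"] + 1}
                             ).head(config.max_profile_features)
    meth = cohort.methylation[["chrom", "position", "beta"]]
    meth_cons = aggregate_methylation(meth, cons_feat, prof_cfg)
    meth_shift = aggregate_methylation(meth, shif_feat, prof_cfg)
    meth_cons.to_frame().to_csv(out / "methylation_conserved.tsv", sep="\t", index=False)
    meth_shift.to_frame().to_csv(out / "methylation_shifted.tsv", sep="\t", index=False)
    half = 50

    def central_per_feature(profile, n_features):
        c = profile.values[profile.flank - half: profile.flank + half + 1]
        return float(c.sum() / max(n_features, 1))

    report["methylation_central_conserved"] = central_per_feature(
        meth_cons, len(cons_feat))
    report["methylation_central_shifted"] = central_per_feature(
        meth_shift, len(shif_feat))

    logger.info("stage enrichment")
    gained_truth = truth.loci.loc[truth.loci["kind"] == KIND_GAINED]
    gained_regions = pd.DataFrame({
        "chrom": gained_truth["chrom"],
        "start": np.maximum(0, gained_truth["pos_tumour"] - 74),
        "end": gained_truth["pos_tumour"] + 74}).reset_index(drop=True)
    gained_frags = report["classification_p1"].gained_b
    if len(gained_frags) and len(gained_regions):
        enr = fisher_enrichment(gained_frags, gained_regions, cohort.genome,
                                seed=config.seed,
                                n_shuffles=config.enrichment_shuffles)
        enr_df = pd.DataFrame([{"fold": enr.fold, "p_value": enr.p_value,
                                "n_query": enr.n_query,
                                "n_overlapping": enr.n_overlapping,
                                "n_random_overlapping": enr.n_random_overlapping,
                                "n_shuffles": enr.n_shuffles}])
    else:
        enr_df = pd.DataFrame([{"fold": np.nan, "p_value": np.nan,
                                "n_query": len(gained_frags), "n_overlapping": 0,
                                "n_random_overlapping": 0,
                                "n_shuffles": config.enrichment_shuffles}])
    enr_df.to_csv(out / "enrichment_gained.tsv", sep="\t", index=False)
    report["enrichment"] = enr_df

    _write_report_md(out, config, report)
    logger.info("run_end_to_end: report written to %s", out)
    return report


def _write_report_md(out: Path, config: PipelineConfig, report: dict) -> None:
    lines = ["# nucleoshift end-to-end report", ""]
    lines.append(f"seed: {config.seed}")
    lines.append("")
    lines.append("## NRL estimates (slope of phaseogram peak regression, bp)")
    lines.append(report["nrl_estimates"].to_string(index=False))
    lines.append("")
    lines.append("## Paired tumour vs normal NRL comparison")
    lines.append(report["paired_nrl"].to_string(index=False))
    lines.append("")
    lines.append("## Repositioning classification (per patient, with truth scores)")
    lines.append(report["classification"].to_string(index=False))
    lines.append("")
    lines.append("## Profiles")
    lines.append(f"occupancy central mean (conserved dyads, +/-50 bp): "
                 f"{report['occupancy_central_mean']:.4f}")
    lines.append(f"methylation central sum per feature, conserved: "
                 f"{report['methylation_central_conserved']:.4f}")
    lines.append(f"methylation central sum per feature, shifted: "
                 f"{report['methylation_central_shifted']:.4f}")
    lines.append("")
    lines.append("## Enrichment of gained nucleosomes in planted gained loci")
    lines.append(report["enrichment"].to_string(index=False))
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))
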