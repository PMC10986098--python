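# nucleoshift

Nucleosome-reorganisation analysis for paired tumour/normal MNase-derived
fragment data, built for epigenomics researchers working with
nucleosome-resolution fragmentomics (tissue MNase-seq, MNase-H3 or
cell-free DNA). The package covers the full desk-side pipeline:

* **fragment-size fractionation** of mapped paired-end fragments into the
  canonical bands (100–120, 120–140, 140–160, 160–180, 180–200 bp, with
  the 120–180 bp mono-nucleosome band as the default analysis set);
* **nucleosome repeat length (NRL) estimation** from dyad-distance
  phaseograms: the frequency distribution *f(d)* of pairwise dyad–dyad
  distances *d* = 1..2000 bp oscillates with period ≈ NRL; peaks *p_k* are
  detected on the smoothed genome-averaged curve and the NRL is the slope
  of the ordinary least-squares regression *p_k = NRL·k + b*, with R² as a
  fit-quality gate, genome-wide or inside region sets (TSS windows, gene
  bodies, padded annotation sets);
* **paired-condition comparison** of per-patient NRL values with the
  paired-sample *t* test;
* **discrete repositioning calls** between two conditions using
  `bedtools intersect` overlap-fraction semantics: *stable* (reproduced at
  ≥ 99 % overlap in another patient), *common* (≥ 99 % match across
  conditions), *shifted* (no reciprocal ≥ 80 % match), *gained*/*lost*
  (zero overlap against the other condition's stable set);
* **aggregate profiles**: per-bp fragment occupancy around feature
  centres, ChIP/Input ratios, and summed CpG beta-value methylation
  profiles;
* **interval enrichment** versus length-preserving random placement with
  a two-sided Fisher exact test;
* a **synthetic cohort generator** that emulates the study design —
  phased nucleosome arrays with condition-specific repeat length, a
  realistic fragment-length mixture including ~20 % dinucleosomes,
  reproducible cross-patient positions, planted gained/lost/shifted
  events and class-linked CpG methylation — with full ground truth for
  parameter-recovery testing.

## Worked example

```python
import pandas as pd
from nucleoshift import (SyntheticConfig, PhaseogramConfig, generate_cohort,
                         estimate_nrl, compare_paired_nrl, classify_pair,
                         evaluate_classification)

cohort = generate_cohort(SyntheticConfig(seed=0), with_sequence=False)
cfg = PhaseogramConfig(min_pairs=1000)
rows = []
for p in (1, 2, 3):
    nrl_n = estimate_nrl(cohort.fragments[(p, "normal")], cfg, size_band=(120, 180))
    nrl_t = estimate_nrl(cohort.fragments[(p, "tumour")], cfg, size_band=(120, 180))
    rows.append({"patient": p, "nrl_a": nrl_n.nrl, "nrl_b": nrl_t.nrl})
table = pd.DataFrame(rows)
print(table.round(2).to_string(index=False))
comp = compare_paired_nrl(table)
print(f"mean NRL difference: {comp.mean_difference:.2f} bp, "
      f"one-sided p = {comp.p_value_one_sided:.2e}")
```

prints

```
 patient  nrl_a  nrl_b
       1  192.7  186.3
       2  193.2  186.4
       3  192.8  185.6
mean NRL difference: 6.80 bp, one-sided p = 5.76e-04
```

The generator planted a 193 bp repeat length in normal and 186 bp in
tumour samples; the estimator recovers both to well under 1 bp and the
paired test detects the 7 bp shortening. Continuing with repositioning
calls for patient 1 (stable positions defined against patients 2 and 3):

```python
classes = classify_pair(cohort.fragments[(1, "normal")], cohort.fragments[(1, "tumour")],
                        [cohort.fragments[(q, "normal")] for q in (2, 3)],
                        [cohort.fragments[(q, "tumour")] for q in (2, 3)])
print(classes.counts)
print(evaluate_classification(cohort.truth, classes))
```

```
{'stable_a': 77793, 'stable_b': 80164, 'common': 30257, 'shifted': 7745,
 'gained_b': 4741, 'lost_b': 3433}
{'gained_recall': 1.0, 'gained_fdr': 0.0, 'lost_recall': 0.955,
 'lost_fdr': 0.0, 'shifted_recall': 1.0}
```

i.e. every planted gained and shifted event and 95 % of lost events are
recovered, with essentially no false discoveries.

## Command line

Every stage is a subcommand of the `nucleoshift` entry point:
`simulate`, `sizes`, `gcwin`, `phaseogram`, `nrl`, `nrl-compare`,
`classify`, `profile`, `methylprofile`, `enrich`, `density` and
`run-all` (the end-to-end driver, which writes per-stage TSVs and a
markdown report). All randomness is controlled by `--seed`; inputs are
plain BED / TSV / FASTA / chrom.sizes files with 0-based half-open
coordinates throughout.

```sh
nucleoshift run-all --seed 0 --out report/
```

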