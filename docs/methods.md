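# Methods

## Coordinates and primitives

All intervals are 0-based, half-open `[start, end)` (BED convention); no
module interprets coordinates otherwise. A fragment's *dyad* — the
inferred nucleosome centre — is the floor midpoint `start + length // 2`.
Even-length fragments have no central base; symmetric alternatives would
shift phaseograms by at most 1 bp, but a single fixed rule is required
for exact, reproducible tests, and the same floor rule is reused for
feature centres in profile computation so the two modules agree.

Fragment-size bins are lower-inclusive, upper-exclusive, so the adjacent
bands 100–120 / 120–140 / … / 180–200 bp are disjoint and partition
[100, 200). The mono-nucleosome analysis band follows the same rule:
[120, 180).

## NRL estimation

The estimator works directly on dyads. Per chromosome, every ordered pair
of dyad positions at distance 1 ≤ d ≤ D (default D = 2000 bp) is counted
with multiplicity; co-located pairs (d = 0) are stored but excluded from
normalisation because they reflect pileup, not spacing. Two filters
precede counting: base pairs carrying more than 50 dyads are discarded
outright (pileup towers are amplification/mapping artefacts; the result
should be and is insensitive to the cutoff when pileups are modest), and
chromosomes deeper than 40 million fragments are uniformly subsampled
under an explicit seed. Chromosomes contributing fewer than `min_pairs`
(default 10,000) pairs are excluded; each remaining chromosome is
normalised to unit mass before an *unweighted* average, so large
chromosomes do not dominate the genome-wide curve.

Peak detection on the averaged curve: a centred moving average of
half-width 10 bp smooths the curve; local maxima (leftmost point of any
plateau) are collected inside the search range [100, D]; maxima whose
topographic prominence is below 5 % of the strongest candidate's are
discarded; the survivors are accepted greedily by decreasing height
(leftmost first on exact ties) subject to a minimum separation of 100 bp
— far below any plausible repeat length, so it only suppresses smoothing
ripple. Because interactive NRL tools rely on manual curation of the peak
list, the automatic procedure adds one declared curation step: walking
left to right, a peak is kept only while its gap from the previous kept
peak lies within ±40 % of the running mean gap (initialised to the first
peak position). This truncates off-lattice maxima produced by
non-spacing structure (in the synthetic substrate, for example, the broad
bump of distances between isolated gained nucleosomes and their
neighbouring arrays) while leaving genuine harmonic series untouched.

The NRL is the slope of ordinary least squares of peak position on peak
order with a free intercept; forcing the line through the origin would
bias the slope whenever the first peak is offset by linker asymmetry. At
least three peaks are required; R² is reported so callers can gate on fit
quality. Region-restricted estimates filter fragments by dyad membership
*before* the phaseogram, so all counted distances are intra-region.

The paired tumour/normal comparison is the classical paired-sample
*t* test on per-patient NRL differences (n − 1 degrees of freedom);
zero-variance differences are reported as degenerate with no p-value.
Both two-sided and one-sided (normal > tumour) p-values are exposed.

## Repositioning classification

Matching follows `bedtools intersect` fraction semantics with `>=`
comparisons, and fractional thresholds are never rounded: the integer
overlap is compared against the real-valued threshold (0.99 × 150 =
148.5, so a 149 bp overlap passes and 147 fails). Stable calling is
non-reciprocal (`-u -f 0.99` against each other patient of the same
condition, one match suffices); common is non-reciprocal at 0.99 against
the other condition's stable set; shifted is the *negation* of a
reciprocal 0.80 match (`-f 0.80 -r -v`); gained/lost require zero overlap
(even 1 bp disqualifies). Common and shifted are computed independently,
leaving an 80–99 % zone with neither label — the class counts are
per-class, not a partition. Interval queries run on a sorted-start index
bounded by the maximum interval length per chromosome; results are
required (and tested over 100 random seeds) to equal brute-force
all-pairs scanning exactly.

## Aggregate profiles

Occupancy profiles accumulate per-bp fragment coverage over the window
[centre − flank, centre + flank] (default flank 2000 bp), mirrored for
minus-strand features, summed over features by default so mass
conservation is exactly testable (the sum over offsets equals the summed
clipped fragment×feature overlap); a per-feature-average flag reproduces
the normalised-average presentation. Depth normalisation divides by
fragments-in-sample per million before smoothing (10 bp window, expanded
to odd width so the average stays centred). ChIP/Input normalisation is a
pointwise ratio with offsets below a minimum input masked as missing, and
profile averaging is available-case (NaN-aware) per offset.

Methylation profiles sum beta values per offset over all (CpG, feature)
pairs with no further normalisation — arbitrary units, comparable only
across feature sets over the same methylation track. Strand orientation
is applied when features carry strands.

## Enrichment

The chance model re-places each query interval uniformly at random on its
own chromosome, preserving length (chromosome composition differs, so
cross-chromosome relocation would conflate composition with position),
optionally avoiding an exclusion set by rejection sampling (1000 attempts,
then a hard error). Ten shuffles are pooled by default into the 2×2 table
[[a, n−a], [R, 10n−R]] (a = observed overlapping queries, R = summed
random overlapping); the fold is the ratio of overlap rates and the
p-value a two-sided Fisher exact test on that table. Counting is
interval-based (a query either overlaps the reference or not), not
bp-based. Under the null the fold calibrates to 1 within ±0.2 at 1000
intervals and 50 shuffles.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, not any
particular tissue: i.i.d. random genomes with per-chromosome GC
probability; phased nucleosome arrays whose dyads sit at
`anchor + k·L + N(0, σ²)` with L = 193 bp in normal and 186 bp in tumour
(a 7 bp shortening, within the reported 5–10 bp range) and σ = 10 bp;
per-nucleosome Poisson coverage (mean 20); a fragment-length mixture of
subnucleosomal (130 ± 10, 15 %), core particle (147 ± 7, 45 %),
chromatosome (168 ± 8, 20 %) and dinucleosome (320 ± 20, 20 %)
components, the last spanning two adjacent dyads so size fractionation
has realistic work to do while the default [120, 180) band excludes it;
three patients sharing each map position with probability 0.9 (±3 bp
jitter otherwise); and 5 % gained, lost and shifted events each, with
shifts of ±60 bp (≥ 25 % of a core fragment).

Three structural choices were made where realism and testability had to
be balanced, and they shape what the defaults can show:

* **Array geometry.** Arrays are 1100 bp (six nucleosomes at 193 bp)
  separated by nucleosome-depleted gaps of 2500 ± 300 bp. Gaps wider than
  the 2000 bp phaseogram window guarantee that inter-array dyad distances
  never alias into the spacing signal; six-nucleosome arrays keep the
  centre-anchored re-spacing drift (below) small enough that planted
  lost/gained events remain geometrically detectable under the
  zero-overlap rule.
* **Condition re-spacing.** Tumour maps reuse each array's jittered
  normal dyads, re-spaced at the tumour repeat length around the array
  midpoint (position k moves by −Δ·(k − (n−1)/2)). This preserves the
  per-locus correspondence that defines events, keeps the conserved-locus
  displacement at ≤ ~18 bp, and leaves the array centre fixed. A
  consequence worth knowing: with Δ = 7 essentially no conserved locus
  stays within the ~1.5 bp needed for a *common* call, so common counts
  in the default Δ = 7 cohort come from the near-identical patient maps,
  and the common label is exercised exactly (fragment-level) in the
  Δ = 0 and unit-test configurations.
* **Shared cut-site pools.** Fragment boundaries at each locus are drawn
  from a small pool (default 6) of candidate (length, centre-offset)
  pairs generated once per locus and shared across patients and
  conditions, emulating the sequence-dependent cut-site preference of
  micrococcal nuclease. Each sampled fragment picks a pool item (or a
  fresh dinucleosome draw). This is what makes cross-patient reproduction
  of fragment coordinates at ~1 bp precision — the basis of stable
  calling — a common event, as it is in deep real data; with fully
  independent per-fragment boundaries the probability of two patients
  producing the same coordinates within 1 bp is vanishingly small at any
  realistic coverage, and stable sets would be empty.

Methylation ties to truth classes: CpGs (CG dinucleotides of the
generated genome) within 74 bp of a conserved dyad draw beta from
N(0.8, 0.1), near a shifted locus from N(0.2, 0.1), elsewhere uniform on
[0, 1]; all clipped to [0, 1].

What the generator does **not** model — and what passing tests therefore
do not show about real data: sequence-dependent nucleosome affinity and
MNase sequence bias beyond the shared pools, mappability and duplicate
structure, copy-number and purity effects in tumours, chromosome-scale
heterogeneity of repeat length, realistic chromosome counts or any real
genome's annotation. Recovery results certify the estimators against
their own generative assumptions, not against tissue biology.

All generation is a pure function of (config, seed): every stage draws
from a named substream of one `numpy` seed sequence, and reruns are
byte-identical (checksummed in the cohort manifest).

## Problem sizes and runtime choices

Tests and the acceptance script run on deliberately compact instances:
default cohorts use two 1.5 Mb chromosomes (~10,000 nucleosome loci,
~120,000 fragments per sample, six samples), NRL parameter-recovery runs
use two 5 Mb chromosomes (~390,000 fragments per sample), and oracle
comparisons use inputs small enough for O(n²) enumeration. These sizes
give the estimators comfortable statistics (recovery errors well under
1 bp) while keeping the full suite around half a minute.

## Degenerate inputs and tie rules

Empty region restrictions, single-dyad tracks and sub-`min_pairs`
chromosomes raise "insufficient data"; fewer than three peaks (before or
after harmonic filtering) raises "too few peaks"; zero-variance paired
differences are degenerate (no p-value); zero random overlap in
enrichment reports an infinite fold with the p-value from the same
table. Position rounding is half-away-from-zero throughout the generator;
peak ties break leftmost; subsampling and shuffling are uniform without
replacement under explicit seeds.

## Known limitations

Peak curation is fully automatic; pathological phaseograms (e.g. strong
sub-NRL periodicity from contaminating fragment families) could defeat
the prominence and harmonic gates, and the R² field exists so callers can
reject such fits. Enrichment is interval-count-based, whereas bp-based
variants weight long intervals differently. Classification supports
exactly two conditions. The per-gene density ranking counts fragments by
dyad membership — any-overlap counting would differ near gene borders.
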