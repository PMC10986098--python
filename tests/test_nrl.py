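import numpy as np
import pandas as pd
import pytest

from nucleoshift import (InsufficientDataError, PhaseogramConfig,
                         SyntheticConfig, TooFewPeaksError, compare_paired_nrl,
                         compute_phaseogram, detect_peaks, estimate_nrl,
                         filter_gene_bodies, fit_nrl, generate_cohort,
                         pad_regions, tss_windows)
from nucleoshift.fragment_ops import DyadTrack

from conftest import make_fragments, make_regions
from oracles import brute_force_pair_counts


def track_from(d, chrom="chr1"):
    pos = np.array(sorted(d), dtype=np.int64)
    cnt = np.array([d[p] for p in pos], dtype=np.int64)
    return DyadTrack({chrom: (pos, cnt)})


SMALL_CFG = PhaseogramConfig(min_pairs=1, max_distance=2000)


class TestPhaseogram:
    def test_regular_lattice_counts(self):
        ph = compute_phaseogram(track_from({0: 1, 190: 1, 380: 1, 570: 1}),
                                SMALL_CFG)
        c = ph.counts["chr1"]
        assert c[190] == 3 and c[380] == 2 and c[570] == 1
        assert c.sum() == 6  # all pairs of 4 dyads

    def test_multiset_pair_multiplicity(self):
        ph = compute_phaseogram(track_from({100: 2, 300: 1}), SMALL_CFG)
        c = ph.counts["chr1"]
        assert c[200] == 2 and c[0] == 1
        assert ph.mean_frequency[199] == pytest.approx(1.0)  # d=0 excluded

    def test_single_position_insufficient(self):
        with pytest.raises(InsufficientDataError):
            compute_phaseogram(track_from({175: 1}), SMALL_CFG)

    def test_normalised_curves_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = {int(p): int(c) for p, c in
             zip(rng.integers(0, 30_000, 400), rng.integers(1, 5, 400))}
        ph = compute_phaseogram(track_from(d), SMALL_CFG)
        assert ph.mean_frequency.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        d = {}
        for p, c in zip(rng.integers(0, 10_000, n), rng.integers(1, 6, n)):
            d[int(p)] = int(c)
        ph = compute_phaseogram(track_from(d), PhaseogramConfig(min_pairs=1,
                                                                max_distance=3000))
        pos = np.array(sorted(d))
        cnt = np.array([d[p] for p in pos])
        assert np.array_equal(ph.counts["chr1"],
                              brute_force_pair_counts(pos, cnt, 3000))

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        d = {int(p): int(c) for p, c in
             zip(rng.integers(0, 20_000, 200), rng.integers(1, 4, 200))}
        shifted = {p + 12_345: c for p, c in d.items()}
        a = compute_phaseogram(track_from(d), SMALL_CFG).counts["chr1"]
        b = compute_phaseogram(track_from(shifted), SMALL_CFG).counts["chr1"]
        assert np.array_equal(a, b)

    def test_average_is_unweighted_mean_of_chromosomes(self):
        t = DyadTrack({"c1": (np.array([0, 200, 400]), np.array([1, 1, 1])),
                       "c2": (np.array([0, 300]), np.array([5, 5]))})
        ph = compute_phaseogram(t, PhaseogramConfig(min_pairs=1, max_distance=500))
        manual = (ph.frequency["c1"] + ph.frequency["c2"]) / 2
        assert np.allclose(ph.mean_frequency, manual)


class TestPeakDetection:
    def test_damped_cosine_peaks_near_period_multiples(self):
        d = np.arange(1, 2001)
        curve = np.cos(2 * np.pi * d / 190.0) * np.exp(-d / 1000.0)
        cfg = PhaseogramConfig(smoothing_half_width=0, min_pairs=1)
        peaks = detect_peaks(curve, cfg)
        assert len(peaks) == 10
        for k, p in enumerate(peaks, start=1):
            # analytic maximum of the damped cosine: slightly left of k*190
            window = np.arange(k * 190 - 40, k * 190 + 40)
            oracle = window[np.argmax(np.cos(2 * np.pi * window / 190.0)
                                      * np.exp(-window / 1000.0))]
            assert abs(p - oracle) <= 1

    def test_flat_curve_has_no_peaks(self):
        with pytest.raises(TooFewPeaksError):
            detect_peaks(np.ones(2000), PhaseogramConfig(min_pairs=1))

    def test_equal_maxima_beyond_separation_both_kept(self):
        y = np.zeros(2000)
        for centre in (400, 550, 700):  # 150 apart > min separation 100
            y[centre - 1] = 1.0
        cfg = PhaseogramConfig(smoothing_half_width=0, min_pairs=1,
                               min_prominence_fraction=0.0)
        peaks = detect_peaks(y, cfg)
        assert set(peaks) == {400, 550, 700}


class TestNrlFit:
    @pytest.mark.parametrize("peaks, slope", [
        ([190, 380, 570], 190.0),
        ([188, 379, 571], 191.5),     # closed form: (p3 - p1) / 2
        ([200, 400, 600, 800], 200.0),
    ])
    def test_regression_slope(self, peaks, slope):
        est = fit_nrl(peaks)
        assert est.nrl == pytest.approx(slope)

    def test_exact_lattice_perfect_fit(self):
        est = fit_nrl([190, 380, 570])
        assert est.intercept == pytest.approx(0.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(TooFewPeaksError):
            fit_nrl([190, 380])


@pytest.fixture(scope="module")
def cohort():
    cfg = SyntheticConfig(seed=9, chromosomes=(("chr1", 600_000, 0.4),))
    return generate_cohort(cfg, with_sequence=False)


class TestEstimateNrl:
    def test_parameter_recovery(self, cohort):
        est = estimate_nrl(cohort.fragments[(1, "normal")],
                           PhaseogramConfig(min_pairs=1000),
                           size_band=(120, 180))
        assert abs(est.nrl - 193.0) <= 2.0
        assert est.r_squared > 0.99

    def test_region_restriction_preserves_estimate(self, cohort):
        loci = cohort.truth.loci
        regions = make_regions(
            [(c, max(0, int(p) - 600), int(p) + 600)
             for c, p in zip(loci["chrom"], loci["pos_normal"]) if p >= 0])
        est = estimate_nrl(cohort.fragments[(1, "normal")],
                           PhaseogramConfig(min_pairs=1000),
                           regions=regions, size_band=(120, 180))
        assert abs(est.nrl - 193.0) <= 2.0

    def test_regions_without_fragments_insufficient(self, cohort):
        regions = make_regions([("chrZ", 0, 1000)])
        with pytest.raises(InsufficientDataError):
            estimate_nrl(cohort.fragments[(1, "normal")],
                         PhaseogramConfig(min_pairs=1000), regions=regions)

    def test_provenance_records_attrition(self, cohort):
        est = estimate_nrl(cohort.fragments[(1, "normal")],
                           PhaseogramConfig(min_pairs=1000),
                           size_band=(120, 180))
        prov = est.provenance
        assert prov["n_after_size_band"] <= prov["n_input"]
        assert prov["n_after_stack_filter"] <= prov["n_after_cap"]


class TestRegionPresets:
    def test_tss_windows_plus_strand(self):
        tss = make_regions([("chr1", 10_000, 10_001, "g", 0, "+")])
        out = tss_windows(tss, flank=5000)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (5000, 15_000)

    def test_tss_windows_require_strand(self):
        tss = make_regions([("chr1", 10_000, 10_001)])
        with pytest.raises(ValueError, match="strand"):
            tss_windows(tss)

    def test_gene_length_bounds_are_strict(self):
        genes = make_regions([("c", 0, 900), ("c", 0, 1001),
                              ("c", 0, 199_999), ("c", 0, 200_000)])
        kept = filter_gene_bodies(genes)
        assert sorted(kept["end"].tolist()) == [1001, 199_999]

    def test_padding_clips_at_zero(self, two_chrom_genome):
        out = pad_regions(make_regions([("chr1", 500, 800)]), pad=1000,
                          genome=two_chrom_genome)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 1800)


class TestPairedComparison:
    def test_mean_difference(self):
        t = pd.DataFrame({"patient": [1, 2, 3], "nrl_a": [193, 192, 195],
                          "nrl_b": [186, 185, 188]})
        comp = compare_paired_nrl(t)
        assert comp.mean_difference == pytest.approx(7.0)

    def test_identical_pairs_degenerate(self):
        t = pd.DataFrame({"patient": [1, 2], "nrl_a": [190, 195],
                          "nrl_b": [190, 195]})
        comp = compare_paired_nrl(t)
        assert comp.degenerate and comp.p_value is None

    def test_t_statistic_matches_definition(self):
        a = np.array([10.0, 12.0, 11.0, 13.0])
        b = np.array([8.0, 9.0, 10.0, 10.0])
        comp = compare_paired_nrl(pd.DataFrame(
            {"patient": [1, 2, 3, 4], "nrl_a": a, "nrl_b": b}))
        # textbook computation from the definition
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy import stats
        p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
        assert comp.t_statistic == pytest.approx(t, abs=1e-9)
        assert comp.p_value == pytest.approx(p, abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_nrl(pd.DataFrame(
                {"patient": [1], "nrl_a": [190.0], "nrl_b": [186.0]}))
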