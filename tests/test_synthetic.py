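import numpy as np
import pandas as pd
import pytest

from nucleoshift import (ProfileConfig, SyntheticConfig, aggregate_methylation,
                         generate_cohort, generate_fragments, generate_genome,
                         generate_methylation, generate_nucleosome_maps)

TINY = dict(chromosomes=(("chr1", 200_000, 0.4),))


class TestGenome:
    def test_gc_fraction_within_binomial_bound(self):
        cfg = SyntheticConfig(seed=3, chromosomes=(("c", 1_000_000, 0.5),))
        g = generate_genome(cfg)
        seq = g.sequence("c", 0, 1_000_000)
        gc = (seq.count("G") + seq.count("C")) / 1_000_000
        assert abs(gc - 0.5) <= 0.0015  # 3 sigma of binomial(1e6, .5)

    def test_zero_gc_probability_is_all_at(self):
        cfg = SyntheticConfig(seed=3, chromosomes=(("c", 10_000, 0.0),))
        g = generate_genome(cfg)
        assert set(g.sequence("c", 0, 10_000)) <= {"A", "T"}

    def test_same_seed_identical_fasta(self, tmp_path):
        cfg = SyntheticConfig(seed=5, chromosomes=(("c", 20_000, 0.45),))
        generate_genome(cfg, fasta_path=tmp_path / "a.fa")
        generate_genome(cfg, fasta_path=tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


class TestMaps:
    def test_zero_jitter_exact_spacing(self):
        cfg = SyntheticConfig(seed=1, jitter_sd=0.01, nrl_normal=190.0,
                              nrl_delta=0.0, gained_fraction=0, lost_fraction=0,
                              shifted_fraction=0, array_length=1900,
                              **TINY)
        truth = generate_nucleosome_maps(cfg)
        first = truth.loci.loc[(truth.loci["array"] == 0)
                               & (truth.loci["chrom"] == "chr1")]
        assert len(first) == 10
        assert np.allclose(np.diff(first["pos_normal"]), 190, atol=1)

    def test_null_config_tumour_equals_normal(self):
        cfg = SyntheticConfig(seed=2, nrl_delta=0.0, gained_fraction=0,
                              lost_fraction=0, shifted_fraction=0, **TINY)
        truth = generate_nucleosome_maps(cfg)
        assert (truth.loci["kind"] == "conserved").all()
        assert truth.loci["pos_normal"].equals(truth.loci["pos_tumour"])

    def test_event_fractions_roughly_respected(self):
        cfg = SyntheticConfig(seed=4, chromosomes=(("chr1", 2_000_000, 0.4),))
        truth = generate_nucleosome_maps(cfg)
        n_array_loci = int((truth.loci["kind"] != "gained").sum())
        for kind, frac in (("lost", 0.05), ("shifted", 0.05)):
            n = int((truth.loci["kind"] == kind).sum())
            sd = np.sqrt(n_array_loci * frac * (1 - frac))
            assert abs(n - frac * n_array_loci) <= 4 * sd
        assert int((truth.loci["kind"] == "gained").sum()) == round(
            0.05 * n_array_loci)

    def test_event_positions_disjoint_and_sorted_truth(self):
        cfg = SyntheticConfig(seed=4, **TINY)
        truth = generate_nucleosome_maps(cfg)
        ev = truth.events
        # one kind per locus: no coordinate appears under two kinds
        key = ev["chrom"] + ":" + ev["pos_normal"].astype(str)
        real = ev.loc[ev["pos_normal"] >= 0]
        assert real.groupby(["chrom", "pos_normal"])["kind"].nunique().max() == 1

    def test_unorderable_arrays_rejected(self):
        with pytest.raises(ValueError, match="unordered"):
            SyntheticConfig(nrl_normal=15.0, jitter_sd=10.0)


class TestFragments:
    def test_fragment_count_poisson_bound(self):
        cfg = SyntheticConfig(seed=6, **TINY)
        truth = generate_nucleosome_maps(cfg)
        frags = generate_fragments(truth, cfg)
        n_loci = int((truth.loci["pos_normal"] >= 0).sum())
        expected = n_loci * cfg.coverage
        got = len(frags[(1, "normal")])
        assert abs(got - expected) <= 4 * np.sqrt(expected) + 0.05 * expected

    def test_pure_core_mixture_gives_147_bp(self):
        cfg = SyntheticConfig(seed=6, fragment_mixture=((147.0, 0.0, 1.0),),
                              **TINY)
        truth = generate_nucleosome_maps(cfg)
        frags = generate_fragments(truth, cfg)[(1, "normal")]
        lengths = (frags["end"] - frags["start"]).unique()
        assert lengths.tolist() == [147]

    def test_length_histogram_has_expected_modes(self):
        cfg = SyntheticConfig(seed=7, chromosomes=(("chr1", 600_000, 0.4),))
        truth = generate_nucleosome_maps(cfg)
        frags = generate_fragments(truth, cfg)[(1, "normal")]
        lengths = (frags["end"] - frags["start"]).to_numpy()
        hist = np.bincount(lengths, minlength=400)
        # core and chromatosome modes, and a dinucleosome shoulder
        assert hist[140:155].max() > hist[155:163].max()
        assert hist[160:176].max() > hist[180:200].max()
        assert hist[300:340].sum() > 0.1 * len(lengths)

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=8, **TINY)
        t1 = generate_nucleosome_maps(cfg)
        t2 = generate_nucleosome_maps(cfg)
        f1 = generate_fragments(t1, cfg)[(2, "tumour")]
        f2 = generate_fragments(t2, cfg)[(2, "tumour")]
        assert f1.equals(f2)


class TestMethylation:
    def test_zero_sd_conserved_cpg_beta_exact(self):
        cfg = SyntheticConfig(seed=9, meth_beta_sd=0.0,
                              chromosomes=(("chr1", 150_000, 0.5),))
        genome = generate_genome(cfg)
        truth = generate_nucleosome_maps(cfg, genome)
        meth = generate_methylation(truth, genome, cfg)
        cons = meth.loc[meth["class"] == "conserved", "beta"]
        assert len(cons) > 0 and (cons == 0.8).all()
        shif = meth.loc[meth["class"] == "shifted", "beta"]
        assert (shif == 0.2).all()

    def test_all_at_genome_has_no_cpgs(self):
        cfg = SyntheticConfig(seed=9, chromosomes=(("chr1", 150_000, 0.0),))
        genome = generate_genome(cfg)
        truth = generate_nucleosome_maps(cfg, genome)
        meth = generate_methylation(truth, genome, cfg)
        assert len(meth) == 0

    def test_conserved_profile_higher_than_shifted(self):
        cfg = SyntheticConfig(seed=10, chromosomes=(("chr1", 400_000, 0.45),))
        genome = generate_genome(cfg)
        truth = generate_nucleosome_maps(cfg, genome)
        meth = generate_methylation(truth, genome, cfg)[
            ["chrom", "position", "beta"]]
        mk = lambda df: pd.DataFrame({"chrom": df["chrom"],
                                      "start": df["position"],
                                      "end": df["position"] + 1})
        cons = mk(truth.dyads("normal", kinds=["conserved"]).head(400))
        shif = mk(truth.loci.loc[truth.loci["kind"] == "shifted",
                                 ["chrom", "pos_normal"]].rename(
                                     columns={"pos_normal": "position"}))
        cfg_p = ProfileConfig(flank=200, smoothing_window=1)
        p_cons = aggregate_methylation(meth, cons, cfg_p)
        p_shif = aggregate_methylation(meth, shif, cfg_p)
        central = slice(p_cons.flank - 50, p_cons.flank + 51)
        mean_cons = p_cons.values[central].sum() / p_cons.n_features
        mean_shif = p_shif.values[central].sum() / p_shif.n_features
        assert mean_cons > 1.5 * mean_shif


class TestCohort:
    def test_default_design_six_sample_beds(self, tmp_path):
        cfg = SyntheticConfig(seed=11, **TINY)
        cohort = generate_cohort(cfg, out_dir=tmp_path / "c")
        beds = [p for name, p in cohort.paths.items() if name.endswith(".bed")]
        assert len(beds) == 6
        assert all(p.exists() for p in beds)

    def test_manifest_checksums_reproducible(self, tmp_path):
        cfg = SyntheticConfig(seed=12, **TINY)
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        ma = (tmp_path / "a" / "manifest.tsv").read_text()
        mb = (tmp_path / "b" / "manifest.tsv").read_text()
        assert ma == mb

    def test_truth_nrl_echoes_config(self, tmp_path):
        cfg = SyntheticConfig(seed=13, nrl_normal=193.0, nrl_delta=7.0, **TINY)
        cohort = generate_cohort(cfg, out_dir=tmp_path / "c", with_sequence=False)
        t = pd.read_csv(cohort.paths["truth_nrl.tsv"], sep="\t")
        assert dict(zip(t["condition"], t["nrl"])) == {"normal": 193.0,
                                                       "tumour": 186.0}
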