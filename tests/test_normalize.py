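import numpy as np
import pytest

import nicscreen as ns
from nicscreen.normalize import SampleNotAnalyzableError, _finite_mean
from tests.conftest import whole_chrom_event


def make_counts(values, sample_id="s"):
    return ns.BinCounts(sample_id=sample_id, source="SCM", counts=values)


class TestFilterBins:
    def test_clean_sample_passes_everything(self, small_genome):
        bc = make_counts(np.full(small_genome.n_bins, 100))
        _, mask = ns.filter_bins(bc, small_genome)
        assert mask.all()

    def test_zero_panel_median_masks_exactly_that_bin(self, small_genome):
        n = small_genome.n_bins
        median = np.ones(n)
        median[17] = 0.0
        panel = ns.ReferencePanel(median_xx=median, median_xy=median,
                                  n_samples=5, cv_cutoff=0.3)
        bc = make_counts(np.full(n, 100))
        _, mask = ns.filter_bins(bc, small_genome, panel=panel)
        assert not mask[17]
        assert mask.sum() == n - 1

    def test_heavy_dropout_is_not_analyzable(self, small_genome):
        rng = np.random.default_rng(0)
        counts = np.full(small_genome.n_bins, 100)
        counts[rng.random(small_genome.n_bins) < 0.6] = 0
        with pytest.raises(SampleNotAnalyzableError, match="not analyzable"):
            ns.filter_bins(make_counts(counts), small_genome)


class TestGcCorrect:
    def test_constant_gc_changes_nothing_but_scale(self, small_genome):
        g = ns.GenomeBins(chrom=small_genome.chrom, start=small_genome.start,
                          end=small_genome.end, gc=np.full(small_genome.n_bins, 0.41),
                          usable=small_genome.usable)
        counts = make_counts(np.arange(1, g.n_bins + 1) * 3)
        out = ns.gc_correct(counts, g)
        ratio = out / counts.counts
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_injected_linear_bias_is_removed(self, small_genome):
        depth = np.round(100 * (1 + 2 * (small_genome.gc - 0.4))).astype(int)
        out = ns.gc_correct(make_counts(depth), small_genome)
        auto = small_genome.is_autosome & np.isfinite(out)
        r = np.corrcoef(out[auto], small_genome.gc[auto])[0, 1]
        assert abs(r) < 0.05
        # mean autosomal depth preserved
        assert np.nanmean(out[small_genome.is_autosome]) == pytest.approx(
            depth[small_genome.is_autosome].mean(), rel=1e-6)

    def test_deterministic_for_identical_input(self, small_genome, scm_profile):
        bc = ns.simulate_sample(ns.SampleKaryotype("XX"), scm_profile, small_genome, seed=5)
        a = ns.gc_correct(bc, small_genome)
        b = ns.gc_correct(bc, small_genome)
        np.testing.assert_array_equal(a, b)

    def test_all_zero_counts_error(self, small_genome):
        with pytest.raises(ValueError):
            ns.gc_correct(make_counts(np.zeros(small_genome.n_bins, int)), small_genome)

    def test_too_few_bins_error(self, small_genome):
        counts = np.full(small_genome.n_bins, 100)
        mask = np.zeros(small_genome.n_bins, bool)
        mask[:50] = True
        with pytest.raises(SampleNotAnalyzableError):
            ns.gc_correct(make_counts(counts), small_genome, mask)


class TestBuildPanel:
    def test_identical_samples_reproduce_profile(self, small_genome):
        depth = np.full(small_genome.n_bins, 80.0)
        panel = ns.build_panel([depth] * 5, small_genome,
                               sexes=["XX", "XX", "XX", "XY", "XY"])
        auto = small_genome.is_autosome
        np.testing.assert_allclose(panel.median_xx[auto], 1.0)

    def test_median_robust_to_single_outlier(self, small_genome):
        depths = [np.full(small_genome.n_bins, 80.0) for _ in range(5)]
        depths[0] = depths[0].copy()
        depths[0][10] *= 2  # one doubled bin in one sample
        # cv_cutoff disabled to isolate the median property (the default
        # cutoff would flag the bin as over-dispersed instead)
        panel = ns.build_panel(depths, small_genome, sexes=["XX"] * 3 + ["XY"] * 2,
                               cv_cutoff=np.inf)
        assert panel.median_xx[10] == pytest.approx(1.0)

    def test_fewer_than_three_samples_error(self, small_genome):
        with pytest.raises(ValueError):
            ns.build_panel([np.ones(small_genome.n_bins)] * 2, small_genome)

    def test_zero_cv_cutoff_masks_all_noisy_bins(self, small_genome, scm_profile):
        counts, _ = ns.simulate_reference_panel(5, scm_profile, small_genome, seed=2)
        depths = [ns.gc_correct(c, small_genome) for c in counts]
        with pytest.raises((ValueError, SampleNotAnalyzableError)):
            ns.build_panel(depths, small_genome, cv_cutoff=0.0)

    def test_sex_inference_from_y_coverage(self, small_genome, scm_profile):
        counts, truths = ns.simulate_reference_panel(6, scm_profile, small_genome, seed=4)
        depths = [ns.gc_correct(c, small_genome) for c in counts]
        from nicscreen.normalize import _infer_panel_sexes
        auto = small_genome.is_autosome
        norm = np.vstack([d / np.nanmedian(d[auto]) for d in depths])
        assert _infer_panel_sexes(norm, small_genome) == [t.sex for t in truths]


class TestReferenceNormalize:
    def test_sample_equal_to_panel_gives_unit_ratio(self, small_genome):
        depth = np.full(small_genome.n_bins, 60.0)
        panel = ns.build_panel([depth] * 4, small_genome, sexes=["XX", "XY", "XX", "XY"])
        profile = ns.reference_normalize(depth, panel, small_genome)
        auto_valid = small_genome.is_autosome & profile.valid
        np.testing.assert_allclose(profile.ratio[auto_valid], 1.0, rtol=1e-12)

    def test_autosomal_median_anchored_to_one(self, fitted_normalizer, full_genome, scm_profile):
        truth = ns.SampleKaryotype("XX", (whole_chrom_event(full_genome, "16", 1),))
        bc = ns.simulate_sample(truth, scm_profile, full_genome, seed=13)
        profile = fitted_normalizer.transform_profile(bc)
        auto_valid = full_genome.is_autosome & profile.valid
        assert abs(np.median(profile.ratio[auto_valid]) - 1.0) < 1e-12

    def test_scale_invariance(self, small_genome, scm_profile):
        counts, _ = ns.simulate_reference_panel(6, scm_profile, small_genome, seed=6)
        norm = ns.CopyRatioNormalizer(genome=small_genome).fit(counts)
        bc = ns.simulate_sample(ns.SampleKaryotype("XY"), scm_profile, small_genome, seed=7)
        p1 = norm.transform_profile(bc)
        scaled = ns.BinCounts(sample_id="s", source="SCM", counts=bc.counts * 3)
        p2 = norm.transform_profile(scaled)
        np.testing.assert_allclose(
            p1.ratio[p1.valid], p2.ratio[p2.valid], rtol=1e-9)


class TestCopyRatioNormalizerEstimator:
    def test_sklearn_params_roundtrip(self, small_genome):
        norm = ns.CopyRatioNormalizer(genome=small_genome, gc_span=0.25)
        params = norm.get_params()
        assert params["gc_span"] == 0.25
        norm.set_params(cv_cutoff=0.5)
        assert norm.cv_cutoff == 0.5

    def test_transform_matrix_shape(self, small_genome, scm_profile):
        counts, _ = ns.simulate_reference_panel(6, scm_profile, small_genome, seed=9)
        norm = ns.CopyRatioNormalizer(genome=small_genome).fit(counts)
        X = np.vstack([c.counts for c in counts[:2]])
        R = norm.transform(X)
        assert R.shape == (2, small_genome.n_bins)
        auto = small_genome.is_autosome
        assert np.nanmedian(R[0, auto]) == pytest.approx(1.0, abs=1e-9)

    def test_unfitted_transform_raises(self, small_genome):
        norm = ns.CopyRatioNormalizer(genome=small_genome)
        with pytest.raises(RuntimeError):
            norm.transform_profile(make_counts(np.ones(small_genome.n_bins, int)))


def test_gc_invariance_across_replicates(small_genome):
    """After correction the depth-GC correlation is negligible in nearly all
    seeded replicates of a GC-biased euploid sample."""
    profile = ns.SourceProfile(gc_bias_strength=1.5)
    ok = 0
    for seed in range(10):
        bc = ns.simulate_sample(ns.SampleKaryotype("XX"), profile, small_genome, seed=seed)
        out = ns.gc_correct(bc, small_genome)
        sel = small_genome.is_autosome & np.isfinite(out)
        r = np.corrcoef(out[sel], small_genome.gc[sel])[0, 1]
        ok += abs(r) < 0.05
    assert ok >= 9


def test_finite_mean_of_empty_is_nan():
    assert np.isnan(_finite_mean(np.array([np.nan, np.nan])))
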