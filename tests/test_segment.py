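import numpy as np
import pytest
from hypothesis import given, strategies as st

import nicscreen as ns
from nicscreen.segment import _batch_max_t, _max_abs_t


def brute_force_max_t(x, min_width=1):
    """Independent O(n^2) enumeration of every admissible arc.

    An arc and its complement describe the same split with mathematically
    equal |T|; ties (within float rounding) break to smallest i, then j.
    """
    x = np.asarray(x, float)
    n = len(x)
    sq = float(np.dot(x, x))
    results = []
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < 1 or k > n - 1:
                continue
            left, right = i, n - j
            if min_width > 1:
                if k < min_width:
                    continue
                if (0 < left < min_width) or (0 < right < min_width):
                    continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            m1, m2 = arc.mean(), comp.mean()
            ss = ((arc - m1) ** 2).sum() + ((comp - m2) ** 2).sum()
            if ss <= 1e-12 * max(sq, 1.0):
                t = np.inf if abs(m1 - m2) > 0 else 0.0
            else:
                s2 = ss / (n - 2)
                t = abs(m1 - m2) / np.sqrt(s2 * (1 / k + 1 / (n - k)))
            results.append((i, j, t))
    tmax = max(t for _, _, t in results)
    if not tmax > 0:
        return (0, n, 0.0)
    for i, j, t in results:  # already in (i, j)-sorted order
        if t == np.inf if np.isinf(tmax) else t >= tmax * (1 - 1e-12):
            return (i, j, t)


class TestMaxTArc:
    def test_matches_brute_force_on_200_random_vectors(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(4, 26))
            x = rng.normal(1.0, 0.2, n)
            if trial % 3 == 0:  # inject a shift in some
                a, b = sorted(rng.integers(0, n, 2))
                x[a:b] += 0.6
            i, j, t = ns.max_t_arc(x)
            oi, oj, ot = brute_force_max_t(x)
            assert (i, j) == (oi, oj)
            assert t == pytest.approx(ot, rel=1e-9)

    def test_step_region_is_the_best_arc(self):
        i, j, t = ns.max_t_arc(np.array([0, 0, 0, 1, 1, 1, 0, 0, 0], float))
        assert (i, j) == (3, 6)
        assert t == np.inf  # perfect two-level split

    def test_constant_vector_has_zero_statistic(self):
        assert ns.max_t_arc(np.ones(8)) == (0, 8, 0.0)

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            ns.max_t_arc(np.ones(3))

    @given(st.integers(0, 1000))
    def test_batched_statistic_agrees_with_arc_matrix(self, seed):
        """The fast per-length search used inside the permutation test must
        equal the full arc-matrix maximum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        x = rng.normal(0, 1, n)
        for mw in (1, 3):
            _, _, t_full = _max_abs_t(x, mw)
            t_batch = _batch_max_t(x[None, :], mw)[0]
            assert t_batch == pytest.approx(t_full, rel=1e-9)


class TestPermutationPvalue:
    def test_constant_input_gives_p_one(self):
        assert ns.permutation_pvalue(np.ones(10), 0.0, n_perm=200, seed=1) == 1.0

    def test_strong_step_is_significant(self):
        x = np.concatenate([np.zeros(15), np.full(15, 10.0)]) + \
            np.random.default_rng(3).normal(0, 1, 30)
        _, _, t = ns.max_t_arc(x)
        p = ns.permutation_pvalue(x, t, n_perm=1000, seed=4)
        assert p <= 0.01

    def test_seeded_reproducibility(self):
        x = np.random.default_rng(5).normal(0, 1, 25)
        _, _, t = ns.max_t_arc(x)
        p1 = ns.permutation_pvalue(x, t, n_perm=500, seed=6)
        p2 = ns.permutation_pvalue(x, t, n_perm=500, seed=6)
        assert p1 == p2

    def test_too_few_permutations_error(self):
        with pytest.raises(ValueError):
            ns.permutation_pvalue(np.ones(10), 0.0, n_perm=50, seed=0)


class TestSegmentChromosome:
    def test_constant_chromosome_is_one_segment(self):
        segs = ns.segment_chromosome(np.ones(40), seed=0, chrom="5")
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, 40)
        assert segs[0].pvalue == 1.0

    def test_recovers_step_boundary_within_one_bin(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([np.full(20, 1.0), np.full(20, 1.5)]) + rng.normal(0, 0.05, 40)
        segs = ns.segment_chromosome(x, seed=8, chrom="9")
        assert len(segs) == 2
        assert abs(segs[0].end - 20) <= 1

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        x = rng.normal(1, 0.1, 60)
        x[25:40] += 0.5
        segs = ns.segment_chromosome(x, seed=10)
        assert segs[0].start == 0 and segs[-1].end == len(x)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert sum(s.n_bins for s in segs) == len(x)
        # bin-weighted mean of segment means equals the overall mean
        weighted = sum(s.mean * s.n_bins for s in segs) / len(x)
        assert weighted == pytest.approx(x.mean(), abs=1e-9)

    def test_no_segment_shorter_than_min_width(self):
        rng = np.random.default_rng(11)
        x = rng.normal(1, 0.1, 50)
        x[10:13] += 2.0
        segs = ns.segment_chromosome(x, min_width=3, seed=12)
        assert all(s.n_bins >= 3 for s in segs)

    def test_short_vector_is_single_segment(self):
        segs = ns.segment_chromosome(np.array([1.0, 1.1, 0.9]), seed=0)
        assert len(segs) == 1 and segs[0].pvalue == 1.0


class TestMergeSegments:
    def test_single_segment_unchanged(self):
        seg = ns.Segment("1", 0, 10, 1.2, 0.5)
        assert ns.merge_segments([seg]) == [seg]

    def test_close_means_merge_with_weighted_mean(self):
        a = ns.Segment("1", 0, 10, 1.00)
        b = ns.Segment("1", 10, 15, 1.02)
        merged = ns.merge_segments([a, b], merge_threshold=0.1)
        assert len(merged) == 1
        assert merged[0].mean == pytest.approx((10 * 1.00 + 5 * 1.02) / 15)
        assert (merged[0].start, merged[0].end) == (0, 15)

    def test_distant_means_stay_separate(self):
        a = ns.Segment("1", 0, 10, 1.0)
        b = ns.Segment("1", 10, 15, 1.5)
        assert len(ns.merge_segments([a, b], merge_threshold=0.1)) == 2


class TestSegmentGenome:
    def test_null_false_split_rate_within_bound(self):
        """On seeded euploid chromosomes the per-chromosome false-split rate
        stays within twice the test level."""
        alpha = 0.01
        splits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(1.0, 0.08, 100)
            segs = ns.segment_chromosome(x, alpha=alpha, seed=10_000 + seed)
            splits += len(segs) > 1
        assert splits <= 2 * alpha * 100

    def test_euploid_profile_segments_one_per_chromosome(self, fitted_normalizer,
                                                         full_genome, scm_profile):
        bc = ns.simulate_sample(ns.SampleKaryotype("XX"), scm_profile, full_genome, seed=21)
        profile = fitted_normalizer.transform_profile(bc)
        segmap = ns.segment_genome(profile, full_genome, seed=22)
        present = [c for c, s in segmap.items() if s]
        assert all(len(segmap[c]) == 1 for c in present)
        auto_means = [segmap[c][0].mean for c in present if c not in ("X", "Y")]
        assert np.all(np.abs(np.array(auto_means) - 1) < 0.05)

    def test_same_seed_identical_segmentation(self, small_genome, scm_profile):
        counts, _ = ns.simulate_reference_panel(6, scm_profile, small_genome, seed=23)
        norm = ns.CopyRatioNormalizer(genome=small_genome).fit(counts)
        bc = ns.simulate_sample(ns.SampleKaryotype("XY"), scm_profile, small_genome, seed=24)
        profile = norm.transform_profile(bc)
        a = ns.segment_genome(profile, small_genome, seed=3)
        b = ns.segment_genome(profile, small_genome, seed=3)
        assert a == b
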