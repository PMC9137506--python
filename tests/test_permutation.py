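import numpy as np
import pytest
from scipy import stats
from _oracles import flood_fill_clusters

from permbold import (ConfigurationError, TaskConfig, compute_thresholds,
                      extract_clusters, null_distribution,
                      permute_performance, threshold_map)
from permbold.permutation import (NullDistribution, PermutationEngine,
                                  ThresholdSet, _order_index)
from permbold.simulate import generate_task_sequence, simulate_performance

VOX = (2.5, 2.5, 3.5)


class _IdentityRng:
    @staticmethod
    def permutation(n):
        return np.arange(n)


def _random_Z(n, seed):
    seq = generate_task_sequence(TaskConfig(n_trials=n, seed=seed))
    return simulate_performance(seq, 0.9, 0.85, seed)


class TestPermutePerformance:
    def test_identity_permutation_leaves_Z_unchanged(self):
        Z = _random_Z(50, 0)
        np.testing.assert_array_equal(permute_performance(Z, _IdentityRng()), Z)

    @pytest.mark.parametrize("seed", range(4))
    def test_column_sums_preserved(self, seed):
        Z = _random_Z(100, seed)
        Zp = permute_performance(Z, np.random.default_rng(seed))
        np.testing.assert_array_equal(Zp.sum(axis=0), Z.sum(axis=0))
        assert (Zp.sum(axis=1) == 1).all()

    def test_all_orderings_equally_likely(self):
        """3 distinct one-hot rows: the 6 permutations appear uniformly
        over 60,000 draws (chi-square, alpha = 0.01)."""
        Z = np.eye(4)[:3].astype(int)
        rng = np.random.default_rng(99)
        counts = {}
        n_draws = 60_000
        for _ in range(n_draws):
            key = tuple(np.argmax(permute_performance(Z, rng), axis=1))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        observed = np.array(list(counts.values()))
        chi2 = ((observed - n_draws / 6) ** 2 / (n_draws / 6)).sum()
        assert chi2 < stats.chi2.ppf(0.99, 5)


class TestNullDistribution:
    def test_identity_run_reproduces_true_extremes(self, tiny_cohort):
        cohort, spec = tiny_cohort
        eng = PermutationEngine(cohort, voxel_size_mm=spec.voxel_size_mm)
        true_map = eng.group_map().median_map[eng.group_mask]
        n = cohort[0].bold.shape[-1]
        mx, mn = eng.run_extremes([np.arange(n)] * len(cohort))
        assert mx == pytest.approx(true_map.max())
        assert mn == pytest.approx(true_map.min())

    def test_deterministic_for_fixed_master_seed(self, tiny_null_cohort):
        cohort, spec = tiny_null_cohort
        eng = PermutationEngine(cohort, voxel_size_mm=spec.voxel_size_mm)
        a = eng.null_distribution(5, master_seed=3)
        b = eng.null_distribution(5, master_seed=3)
        np.testing.assert_array_equal(a.maxima, b.maxima)
        np.testing.assert_array_equal(a.minima, b.minima)
        c = eng.null_distribution(5, master_seed=4)
        assert not np.array_equal(a.maxima, c.maxima)

    def test_functional_wrapper_matches_engine(self, tiny_null_cohort):
        cohort, spec = tiny_null_cohort
        nd = null_distribution(cohort, B=3, master_seed=1,
                               voxel_size_mm=spec.voxel_size_mm)
        eng = PermutationEngine(cohort, voxel_size_mm=spec.voxel_size_mm)
        nd2 = eng.null_distribution(3, 1)
        np.testing.assert_array_equal(nd.maxima, nd2.maxima)

    def test_maxima_never_below_minima(self, tiny_null_cohort):
        cohort, spec = tiny_null_cohort
        nd = null_distribution(cohort, B=5, master_seed=0,
                               voxel_size_mm=spec.voxel_size_mm)
        assert (nd.maxima >= nd.minima).all()


class TestThresholds:
    def _nd(self, maxima, minima=None):
        maxima = np.asarray(maxima, float)
        if minima is None:
            minima = maxima - 1 - np.abs(maxima)  # any valid run has max >= min
        return NullDistribution(maxima=maxima, minima=np.asarray(minima, float),
                                master_seed=0)

    def test_default_alphas_give_six_thresholds(self):
        nd = self._nd(np.arange(1, 2001))
        thr = compute_thresholds(nd)
        assert len(thr) == 6
        assert set(thr.upper) == {0.001, 0.01, 0.05}

    def test_degenerate_distribution_collapses_to_constant(self):
        nd = self._nd(np.full(500, 4.2), np.full(500, -1.1))
        thr = compute_thresholds(nd, warn=False)
        assert all(v == 4.2 for v in thr.upper.values())
        assert all(v == -1.1 for v in thr.lower.values())

    @pytest.mark.parametrize("B,alpha", [(1000, 0.05), (199, 0.05),
                                         (1000, 0.001), (357, 0.01)])
    def test_exhaustive_scan_oracle(self, B, alpha):
        """The returned threshold is the smallest observed value whose
        empirical exceedance probability is strictly below alpha."""
        rng = np.random.default_rng(B + int(1000 * alpha))
        maxima = rng.standard_normal(B) * 3 + 1
        nd = self._nd(maxima)
        thr = compute_thresholds(nd, (alpha,), warn=False)
        t = thr.upper[alpha]
        candidates = np.sort(maxima)
        feasible = [c for c in candidates if (maxima > c).sum() / B < alpha]
        assert t == min(feasible)
        # lower tail symmetric
        tl = thr.lower[alpha]
        feas_lo = [c for c in np.sort(nd.minima)
                   if (nd.minima < c).sum() / B < alpha]
        assert tl == max(feas_lo)

    def test_thresholds_nested_in_alpha(self, rng):
        for _ in range(20):
            B = int(rng.integers(100, 1500))
            nd = self._nd(rng.standard_normal(B))
            thr = compute_thresholds(nd, warn=False)
            assert thr.upper[0.001] >= thr.upper[0.01] >= thr.upper[0.05]
            assert thr.lower[0.001] <= thr.lower[0.01] <= thr.lower[0.05]

    def test_low_B_warns(self):
        nd = self._nd(np.arange(100.0))
        with pytest.warns(UserWarning, match="resolution"):
            compute_thresholds(nd, (0.001, 0.05))

    def test_order_index_honors_strict_inequality(self):
        # alpha*B integer: one fewer exceedance than alpha*B
        assert _order_index(1000, 0.05) == 49
        # alpha*B non-integer: floor(alpha*B) exceedances
        assert _order_index(199, 0.05) == 9
        assert _order_index(1000, 0.001) == 0


def _simple_thresholds():
    return ThresholdSet(upper={0.001: 3.0, 0.01: 2.0, 0.05: 1.0},
                        lower={0.001: -3.0, 0.01: -2.0, 0.05: -1.0})


class TestThresholdMap:
    def test_subthreshold_map_is_all_zero(self, rng):
        vol = rng.uniform(-0.99, 0.99, size=(5, 5, 4))
        assert not threshold_map(vol, _simple_thresholds()).any()

    def test_most_stringent_tier_wins(self):
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0] = 5.0    # above every upper threshold
        vol[1, 1, 1] = 1.5    # only above the 0.05 tier
        vol[2, 2, 2] = -2.5   # below the 0.01 lower cutoff
        labels = threshold_map(vol, _simple_thresholds())
        assert labels[0, 0, 0] == 3
        assert labels[1, 1, 1] == 1
        assert labels[2, 2, 2] == -2

    def test_label_counts_match_direct_comparisons(self, rng):
        vol = rng.standard_normal((8, 8, 6)) * 2
        thr = _simple_thresholds()
        labels = threshold_map(vol, thr)
        for tier, a in [(1, 0.05), (2, 0.01), (3, 0.001)]:
            up = thr.upper[a]
            stricter = [thr.upper[b] for b in (0.001, 0.01, 0.05)
                        if b < a]
            upper_exact = (vol > up)
            if stricter:
                upper_exact &= ~(vol > min(stricter))
            assert (labels == tier).sum() == upper_exact.sum()


class TestExtractClusters:
    def test_empty_image_gives_no_clusters(self):
        assert extract_clusters(np.zeros((4, 4, 4), int), VOX) == []

    def test_size_filter_is_strict(self):
        # 21.875 mm^3 per voxel: 7 voxels = 153 mm^3, 4 voxels = 87.5 mm^3
        sig = np.zeros((12, 12, 6), int)
        sig[1:8, 1, 1] = 1          # 7-voxel line
        sig[10, 1:5, 1] = 1         # 4-voxel line
        recs = extract_clusters(sig, VOX, connectivity=6, min_size_mm3=100.0)
        assert len(recs) == 1
        assert recs[0].size_voxels == 7

    def test_exactly_min_size_is_excluded(self):
        sig = np.zeros((8, 8, 8), int)
        sig[0, 0, :4] = 1  # 4 voxels x 25 mm^3 = 100 mm^3 exactly
        assert extract_clusters(sig, (2.5, 2.5, 4.0), min_size_mm3=100.0) == []

    def test_adjacent_opposite_signs_never_merge(self):
        sig = np.zeros((10, 4, 4), int)
        sig[0:5, 0, 0] = 1
        sig[5:10, 0, 0] = -2
        recs = extract_clusters(sig, VOX, connectivity=26, min_size_mm3=100.0)
        assert {r.sign for r in recs} == {"positive", "negative"}
        assert len(recs) == 2

    def test_peak_is_largest_absolute_statistic(self, rng):
        sig = np.zeros((6, 6, 6), int)
        sig[1:4, 1:4, 1:4] = 1
        stat = np.zeros((6, 6, 6))
        stat[1:4, 1:4, 1:4] = rng.uniform(1, 2, size=(3, 3, 3))
        stat[2, 3, 2] = 9.0
        recs = extract_clusters(sig, VOX, stat_map=stat)
        assert recs[0].peak_coord == (2, 3, 2)
        assert recs[0].peak_value == 9.0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            sig = (rng.random((9, 9, 7)) < 0.25).astype(int)
            sig -= 2 * (rng.random((9, 9, 7)) < 0.15).astype(int)
            recs = extract_clusters(sig, VOX, connectivity=connectivity,
                                    min_size_mm3=0.0)
            oracle_sizes = []
            for sel in (sig > 0, sig < 0):
                oracle_sizes += [len(c) for c in
                                 flood_fill_clusters(sel, connectivity)]
            assert sorted(r.size_voxels for r in recs) == sorted(oracle_sizes)

    def test_cluster_count_non_increasing_in_min_size(self, rng):
        sig = (rng.random((12, 12, 8)) < 0.3).astype(int)
        counts = [len(extract_clusters(sig, VOX, min_size_mm3=s))
                  for s in (0, 50, 100, 200, 400)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_clusters(np.zeros((3, 3, 3), int), VOX, connectivity=4)
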