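import numpy as np
import pytest
from scipy import stats

from adiffi import (
    AdiffiConfig,
    adiffi,
    cluster_effect,
    cluster_size_threshold,
    derive_compartment,
    differential_map,
    fisher_lookup,
    fisher_two_sided,
    frequency_map,
    generate_cohort,
    permutation_null,
    suprathreshold_clusters,
    voxelwise_fisher,
)

from conftest import make_effect_spec, make_null_spec


class TestFisherTwoSided:
    def test_degenerate_margins(self):
        assert fisher_two_sided(0, 0, 10, 10) == 1.0

    def test_balanced_table(self):
        assert fisher_two_sided(5, 5, 10, 10) == 1.0

    def test_five_vs_zero(self):
        # support of the 5-success margin has 6 tables; the two-sided sum
        # keeps those with point probability <= P(X=5)
        assert fisher_two_sided(5, 0, 10, 10) == pytest.approx(0.032507739938, rel=1e-9)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fisher_two_sided(11, 0, 10, 10)
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 0, 10, 10)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (5, 8), (8, 8)])
    def test_matches_scipy_exhaustively(self, n1, n2):
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                expected = stats.fisher_exact([[a, n1 - a], [b, n2 - b]]).pvalue
                assert fisher_two_sided(a, b, n1, n2) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("n1,n2", [(4, 4), (6, 9), (12, 7)])
    def test_lookup_matches_scalar(self, n1, n2):
        lut = fisher_lookup(n1, n2)
        for a in range(n1 + 1):
            for b in range(n2 + 1):
                assert lut[a, b] == pytest.approx(fisher_two_sided(a, b, n1, n2), rel=1e-12)


class TestVoxelwiseFisher:
    def test_matches_per_voxel_loop(self, rng):
        shape = (16, 16, 16)
        masks_a = [rng.random(shape) < 0.4 for _ in range(8)]
        masks_b = [rng.random(shape) < 0.4 for _ in range(8)]
        p_map = voxelwise_fisher(masks_a, masks_b)
        ca = np.sum(masks_a, axis=0)
        cb = np.sum(masks_b, axis=0)
        union = np.any(masks_a + masks_b, axis=0)
        for v in np.argwhere(union)[::37]:  # spot-check a stride of voxels
            i, j, k = v
            expected = stats.fisher_exact(
                [[ca[i, j, k], 8 - ca[i, j, k]], [cb[i, j, k], 8 - cb[i, j, k]]]
            ).pvalue
            assert p_map[i, j, k] == pytest.approx(expected, rel=1e-9)
        assert np.all(p_map[~union] == 1.0)

    def test_equal_counts_give_p_one(self, rng):
        masks = [rng.random((8, 8, 8)) < 0.5 for _ in range(6)]
        p_map = voxelwise_fisher(masks, [m.copy() for m in masks])
        assert np.all(p_map == 1.0)

    def test_group_swap_symmetry(self, rng):
        masks_a = [rng.random((10, 10, 10)) < 0.3 for _ in range(7)]
        masks_b = [rng.random((10, 10, 10)) < 0.3 for _ in range(5)]
        assert np.array_equal(
            voxelwise_fisher(masks_a, masks_b), voxelwise_fisher(masks_b, masks_a)
        )

    def test_empty_group_errors(self, rng):
        with pytest.raises(ValueError):
            voxelwise_fisher([], [rng.random((4, 4, 4)) < 0.5])


class TestSuprathresholdClusters:
    def test_no_suprathreshold_voxels(self):
        assert suprathreshold_clusters(np.ones((4, 4, 4)), 0.005, 26) == []

    def test_corner_adjacency_depends_on_connectivity(self):
        p = np.ones((4, 4, 4))
        p[0, 0, 0] = p[1, 1, 1] = 1e-6  # share only a corner
        assert len(suprathreshold_clusters(p, 0.005, 26)) == 1
        assert len(suprathreshold_clusters(p, 0.005, 6)) == 2

    def test_solid_block(self):
        p = np.ones((5, 5, 5))
        p[1:4, 1:4, 1:4] = 1e-4
        clusters = suprathreshold_clusters(p, 0.005, 26)
        assert len(clusters) == 1
        assert clusters[0].size == 27

    def test_strict_inequality_at_threshold(self):
        p = np.ones((3, 3, 3))
        p[1, 1, 1] = 0.005
        assert suprathreshold_clusters(p, 0.005, 26) == []

    def test_sorted_by_size_then_linear_index(self):
        p = np.ones((8, 8, 8))
        p[6, 6, 6] = 1e-6  # singleton, large linear index
        p[0, 0, 0:2] = 1e-6  # pair at the origin
        p[4, 0, 0] = 1e-6  # singleton, smaller linear index
        clusters = suprathreshold_clusters(p, 0.005, 6)
        assert [c.size for c in clusters] == [2, 1, 1]
        assert tuple(clusters[1].indices[0]) == (4, 0, 0)
        assert tuple(clusters[2].indices[0]) == (6, 6, 6)

    def test_min_p_recorded(self):
        p = np.ones((4, 4, 4))
        p[1, 1, 1] = 1e-6
        p[1, 1, 2] = 1e-4
        (c,) = suprathreshold_clusters(p, 0.005, 26)
        assert c.min_p == pytest.approx(1e-6)


class TestClusterSizeThreshold:
    def test_mostly_empty_null(self):
        null = [0] * 96 + [5, 6, 7, 8]
        # 4/100 >= 1 -> 0.04 < 0.05 already at k=1
        assert cluster_size_threshold(null, 0.05) == 1

    def test_ties_at_small_sizes(self):
        null = [0] * 94 + [2] * 6
        # >= 1: 6%, >= 2: 6%, >= 3: 0% -> threshold 3
        assert cluster_size_threshold(null, 0.05) == 3

    def test_all_zero_null(self):
        assert cluster_size_threshold([0] * 100, 0.05) == 1


class TestPermutationNull:
    def test_determinism(self, rng):
        masks = [rng.random((8, 8, 8)) < 0.4 for _ in range(10)]
        is_a = [True] * 5 + [False] * 5
        cfg = AdiffiConfig(n_permutations=30, seed=9)
        null1, k1 = permutation_null(masks, is_a, cfg)
        null2, k2 = permutation_null(masks, is_a, cfg)
        assert np.array_equal(null1, null2)
        assert k1 == k2

    def test_identical_masks_no_signal(self, rng):
        m = rng.random((8, 8, 8)) < 0.5
        masks = [m.copy() for _ in range(10)]
        cfg = AdiffiConfig(n_permutations=25, seed=1)
        null, k = permutation_null(masks, [True] * 5 + [False] * 5, cfg)
        assert np.all(null == 0)
        assert k == 1

    def test_too_few_permutations_warns(self, rng):
        masks = [rng.random((6, 6, 6)) < 0.4 for _ in range(6)]
        cfg = AdiffiConfig(n_permutations=5, seed=0, fwe_alpha=0.05)
        with pytest.warns(UserWarning, match="permutations"):
            permutation_null(masks, [True] * 3 + [False] * 3, cfg)


class TestClusterEffect:
    def _maps(self, va, vb):
        fa = frequency_map([np.ones((2, 2, 2), bool)], "A", "whole_tumor")
        fb = frequency_map([np.ones((2, 2, 2), bool)], "B", "whole_tumor")
        fa.values = np.full((2, 2, 2), float(va))
        fb.values = np.full((2, 2, 2), float(vb))
        return fa, fb

    def test_declared_definition(self):
        fa, fb = self._maps(33.9, 10.0)
        idx = np.argwhere(np.ones((2, 2, 2), bool))
        assert cluster_effect(idx, fa, fb) == pytest.approx(239.0)

    def test_equal_maps_zero_effect(self):
        fa, fb = self._maps(12.5, 12.5)
        idx = np.argwhere(np.ones((2, 2, 2), bool))
        assert cluster_effect(idx, fa, fb) == pytest.approx(0.0)

    def test_scale_invariance(self):
        fa, fb = self._maps(30.0, 12.0)
        fa2, fb2 = self._maps(60.0, 24.0)
        idx = np.argwhere(np.ones((2, 2, 2), bool))
        assert cluster_effect(idx, fa, fb) == pytest.approx(cluster_effect(idx, fa2, fb2))

    def test_zero_reference_undefined(self):
        fa, fb = self._maps(30.0, 0.0)
        idx = np.argwhere(np.ones((2, 2, 2), bool))
        assert cluster_effect(idx, fa, fb) is None


@pytest.fixture(scope="module")
def planted_result():
    spec = make_effect_spec(101, n_a=40, n_b=40)
    cohort, volumes, truth = generate_cohort(spec)
    masks = [derive_compartment(s, "whole_tumor") for s in volumes]
    cfg = AdiffiConfig(n_permutations=60, seed=5)
    res = adiffi(masks[:40], masks[40:], cfg, group_a="MES", group_b="RTK_I")
    return res, truth


class TestAdiffi:
    def test_planted_effect_detected(self, planted_result):
        res, truth = planted_result
        assert res.n_significant_clusters >= 1
        assert res.min_raw_p < res.config.raw_p_threshold
        sig = res.significant_mask()
        assert np.logical_and(sig, truth.effect_region_mask).sum() > 0

    def test_significant_voxels_sum_identity(self, planted_result):
        res, _ = planted_result
        assert res.n_significant_voxels == sum(c.size for c in res.significant_clusters)

    def test_min_raw_p_below_threshold_when_clusters_exist(self, planted_result):
        res, _ = planted_result
        assert res.clusters
        assert res.min_raw_p <= res.config.raw_p_threshold

    def test_cluster_direction_matches_differential(self, planted_result):
        res, _ = planted_result
        for c in res.significant_clusters:
            assert c.direction == np.sign(c.mean_differential)
            # the boosted group is A, so the top cluster should favor A
        assert res.significant_clusters[0].direction == 1

    def test_rank_consistency_with_threshold_decision(self, planted_result):
        res, _ = planted_result
        n = res.config.n_permutations
        observed_max = res.clusters[0].size if res.clusters else 0
        exceed = int(np.count_nonzero(res.null_max_sizes >= observed_max))
        assert res.corrected_p_max_cluster == pytest.approx((1 + exceed) / (n + 1))
        if res.n_significant_clusters > 0:
            assert exceed / n < res.config.fwe_alpha

    def test_group_swap_symmetry(self):
        spec = make_null_spec(55, n_a=6, n_b=6)
        _, volumes, _ = generate_cohort(spec)
        masks = [derive_compartment(s, "whole_tumor") for s in volumes]
        cfg = AdiffiConfig(n_permutations=20, seed=2)
        r_ab = adiffi(masks[:6], masks[6:], cfg, group_a="A", group_b="B")
        r_ba = adiffi(masks[6:], masks[:6], cfg, group_a="B", group_b="A")
        assert np.array_equal(r_ab.p_map, r_ba.p_map)
        assert np.allclose(r_ab.differential.values, -r_ba.differential.values)

    def test_null_cohort_usually_clean(self):
        spec = make_null_spec(77, n_a=10, n_b=10, grid=20)
        _, volumes, truth = generate_cohort(spec)
        assert not truth.effect_region_mask.any()
        masks = [derive_compartment(s, "whole_tumor") for s in volumes]
        res = adiffi(masks[:10], masks[10:], AdiffiConfig(n_permutations=40, seed=0))
        assert res.n_significant_clusters == 0
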