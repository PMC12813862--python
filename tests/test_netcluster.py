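"""Statistic maps, thresholding, neighborhood filter, clustering, permutation."""

import numpy as np
import pytest
from scipy import stats

from oscnet import netcluster as nc
from oscnet.sourcespace import bilateral_source_space, spatial_adjacency
from tests_support_bfs import brute_force_components, neighbor_fn_3d, neighbor_fn_4d


@pytest.fixture(scope="module")
def small_neighbors():
    # single-hemisphere icosahedron (12 locations, every vertex degree 5)
    space = bilateral_source_space(0)
    nbrs = spatial_adjacency(space)
    return {k: {j for j in v if j < 12} for k, v in nbrs.items() if k < 12}


@pytest.fixture(scope="module")
def power_space(small_neighbors):
    return nc.BinSpace.for_power(3, 4, small_neighbors)


@pytest.fixture(scope="module")
def coupling_space(small_neighbors):
    from oscnet.coupling import canonical_pairs

    pairs = canonical_pairs(12)
    return nc.BinSpace.for_coupling(3, 4, pairs, small_neighbors)


class TestStratifyTrials:
    def test_unbalanced_counts_reduced_to_minimum(self, rng):
        labels = np.repeat([0, 1, 2, 3], [50, 30, 30, 30])
        kept = nc.stratify_trials(labels, rng)
        _, counts = np.unique(labels[kept], return_counts=True)
        assert (counts == 30).all()

    def test_equal_counts_keep_everything(self, rng):
        labels = np.repeat([0, 1], 20)
        assert len(nc.stratify_trials(labels, rng)) == 40

    def test_seed_determinism(self):
        labels = np.repeat([0, 1], [25, 40])
        a = nc.stratify_trials(labels, np.random.default_rng(3))
        b = nc.stratify_trials(labels, np.random.default_rng(3))
        assert (a == b).all()


class TestConditionStatMap:
    def test_identical_cells_give_zero_statistic(self):
        x = np.tile(np.random.default_rng(0).standard_normal((10, 1, 6)), (1, 4, 1))
        sm = nc.condition_stat_map(x, "main_a")
        assert np.allclose(sm.values, 0.0)

    def test_paired_design_matches_scipy_ttest_rel(self, rng):
        x = rng.standard_normal((10, 2, 8))
        sm = nc.condition_stat_map(x, "paired")
        expected = stats.ttest_rel(x[:, 0], x[:, 1], axis=0).statistic
        assert np.allclose(sm.values, expected, atol=1e-10)

    def test_two_condition_f_equals_t_squared(self, rng):
        x4 = rng.standard_normal((8, 4, 5))
        # main effect of A with B collapsed == paired t on A-marginals
        t_map = nc.condition_stat_map(
            np.stack([x4[:, :2].mean(1, keepdims=True), x4[:, 2:].mean(1, keepdims=True)], axis=1)[
                :, :, 0, :
            ],
            "paired",
        )
        f_map = nc.condition_stat_map(x4, "main_a")
        assert np.allclose(f_map.values, t_map.values**2, atol=1e-10)

    def test_interaction_f_matches_difference_of_differences_t(self, rng):
        x = rng.standard_normal((9, 4, 7))
        dd = (x[:, 0] - x[:, 1]) - (x[:, 2] - x[:, 3])
        expected = stats.ttest_1samp(dd, 0.0, axis=0).statistic ** 2
        sm = nc.condition_stat_map(x, "interaction")
        assert np.allclose(sm.values, expected, atol=1e-10)


class TestBinarizeMap:
    def test_vanishing_alpha_empties_the_map(self, rng):
        sm = nc.StatMap(rng.standard_normal(50) * 3, "t", np.ones(50), (1, 11))
        assert nc.binarize_map(sm, alpha=1e-12).sum() == 0

    def test_t_threshold_matches_textbook_critical_value(self, rng):
        vals = rng.standard_normal(2000) * 3
        sm = nc.StatMap(vals, "t", np.sign(vals), (1, 28))
        crit = stats.t.ppf(1 - 0.01 / 2, 28)  # n = 29 subjects, two-tailed 0.01
        got = nc.binarize_map(sm, alpha=0.01)
        assert (got == (np.abs(vals) > crit)).all()

    def test_monotone_in_alpha(self, rng):
        vals = rng.standard_normal(500) * 2
        sm = nc.StatMap(vals**2, "F", np.sign(vals), (1, 15))
        tight = nc.binarize_map(sm, 0.01)
        loose = nc.binarize_map(sm, 0.05)
        assert not np.any(tight & ~loose)


class TestNeighborhoodFilter:
    def test_isolated_bin_removed(self, power_space):
        b = np.zeros(power_space.n_bins, bool)
        b[17] = True
        assert nc.neighborhood_filter(b, power_space.adjacency, 0.3).sum() == 0

    def test_fully_surrounded_bin_kept(self, power_space):
        b = np.ones(power_space.n_bins, bool)
        assert nc.neighborhood_filter(b, power_space.adjacency, 0.3).all()

    def test_exactly_at_ratio_kept_inclusive(self):
        # 10-bin chain: ends have 1 neighbor, middles 2; bin with exactly
        # ratio of neighbors significant must survive at ratio 0.5
        import scipy.sparse as sp

        chain = sp.diags([np.ones(9), np.ones(9)], [1, -1], format="csr")
        b = np.zeros(10, bool)
        b[[3, 4]] = True  # each has 1 of 2 neighbors significant = exactly 0.5
        kept = nc.neighborhood_filter(b, chain, 0.5)
        assert kept[3] and kept[4]
        assert nc.neighborhood_filter(b, chain, 0.51).sum() == 0

    def test_counts_use_prefilter_map(self):
        import scipy.sparse as sp

        chain = sp.diags([np.ones(9), np.ones(9)], [1, -1], format="csr")
        b = np.zeros(10, bool)
        b[[0, 1, 2]] = True
        kept = nc.neighborhood_filter(b, chain, 0.5)
        # bin 2's right neighbor (3) is not significant but left (1) is: 1/2 kept;
        # had the filter iterated after removing bin 3's chain it could differ
        assert kept[[0, 1, 2]].all()


class TestExtractClusters:
    def test_single_bin_cluster(self, power_space, rng):
        vals = np.abs(rng.standard_normal(power_space.n_bins))
        b = np.zeros(power_space.n_bins, bool)
        b[31] = True
        sm = nc.StatMap(vals, "t", np.ones(power_space.n_bins), (1, 9))
        (c,) = nc.extract_clusters(b, sm, power_space)
        assert list(c.members) == [31] and c.mass == pytest.approx(vals[31])

    def test_time_adjacent_bins_merge(self, power_space):
        i1 = np.ravel_multi_index((1, 1, 4), power_space.shape)
        i2 = np.ravel_multi_index((1, 2, 4), power_space.shape)
        b = np.zeros(power_space.n_bins, bool)
        b[[i1, i2]] = True
        sm = nc.StatMap(np.ones(power_space.n_bins), "t", np.ones(power_space.n_bins), (1, 9))
        clusters = nc.extract_clusters(b, sm, power_space)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_opposite_signs_never_merge(self, power_space):
        i1 = np.ravel_multi_index((1, 1, 4), power_space.shape)
        i2 = np.ravel_multi_index((1, 2, 4), power_space.shape)
        b = np.zeros(power_space.n_bins, bool)
        b[[i1, i2]] = True
        vals = np.ones(power_space.n_bins)
        vals[i2] = -1.0
        sm = nc.StatMap(vals, "t", np.sign(vals), (1, 9))
        clusters = nc.extract_clusters(b, sm, power_space)
        assert len(clusters) == 2

    @pytest.mark.parametrize("which", ["3d", "4d"])
    def test_random_maps_match_brute_force_bfs(self, which, power_space, coupling_space, small_neighbors):
        space = power_space if which == "3d" else coupling_space
        fn = (neighbor_fn_3d if which == "3d" else neighbor_fn_4d)(space, small_neighbors)
        rng = np.random.default_rng(99)
        for _ in range(25):
            b = rng.random(space.n_bins) < 0.3
            vals = np.abs(rng.standard_normal(space.n_bins)) + 0.1
            sm = nc.StatMap(vals, "t", np.ones(space.n_bins), (1, 9))
            got = {frozenset(c.members.tolist()) for c in nc.extract_clusters(b, sm, space)}
            expected = brute_force_components(b, fn)
            assert got == expected
            for c in nc.extract_clusters(b, sm, space):
                assert c.mass == pytest.approx(vals[c.members].sum())


class TestPermutationTest:
    def test_identical_data_under_all_labels_never_significant(self, power_space, rng):
        base = rng.standard_normal((10, 1, power_space.n_bins))
        x = np.tile(base, (1, 2, 1))
        clusters = nc.permutation_test(x, "paired", power_space, n_perm=200, rng=rng)
        assert all((c.p or 1.0) > 0.05 for c in clusters)

    def test_planted_block_detected(self, power_space, rng):
        x = rng.standard_normal((12, 2, power_space.n_bins))
        block = [np.ravel_multi_index((f, t, u), power_space.shape)
                 for f in (0, 1) for t in (1, 2) for u in (0, 1, 5)]
        x[:, 0, block] += 2.0
        clusters = nc.permutation_test(x, "paired", power_space, n_perm=300, rng=rng)
        top = clusters[0]
        assert top.p <= 0.05 and top.sign == 1
        assert set(block) <= set(top.members.tolist())

    def test_f_and_t_squared_give_identical_clusters(self, rng):
        # 2-condition contrast run as paired t and as a degenerate 2x2 main
        # effect must yield the same clusters at matched thresholds
        space = nc.BinSpace.for_power(2, 3, {0: {1}, 1: {0}})
        x2 = rng.standard_normal((9, 2, space.n_bins))
        x2[:, 0, :3] += 1.5
        x4 = np.stack([x2[:, 0], x2[:, 0], x2[:, 1], x2[:, 1]], axis=1)
        t_clusters = nc.permutation_test(x2, "paired", space, alpha=0.05, n_perm=50, rng=np.random.default_rng(0))
        f_clusters = nc.permutation_test(x4, "main_a", space, alpha=0.05, n_perm=50, rng=np.random.default_rng(0))
        t_sets = {frozenset(c.members.tolist()) for c in t_clusters}
        f_sets = {frozenset(c.members.tolist()) for c in f_clusters}
        assert t_sets == f_sets

    def test_permutation_count_validated(self, power_space, rng):
        x = rng.standard_normal((5, 2, power_space.n_bins))
        with pytest.raises(ValueError):
            nc.permutation_test(x, "paired", power_space, n_perm=0, rng=rng)


class TestProjectCluster:
    def test_single_bin_projection(self, power_space, rng):
        vals = np.abs(rng.standard_normal(power_space.n_bins))
        sm = nc.StatMap(vals, "t", np.ones(power_space.n_bins), (1, 9))
        flat = np.ravel_multi_index((2, 3, 7), power_space.shape)
        c = nc.ClusterResult(np.array([flat]), float(vals[flat]), 1)
        tf = nc.project_cluster(c, sm, power_space, "tf")
        assert tf[2, 3] == pytest.approx(vals[flat]) and tf.sum() == pytest.approx(vals[flat])

    def test_pair_space_projection_accounting_identity(self, coupling_space, rng):
        vals = np.abs(rng.standard_normal(coupling_space.n_bins)) + 0.5
        sm = nc.StatMap(vals, "F", np.ones(coupling_space.n_bins), (1, 9))
        members = rng.choice(coupling_space.n_bins, size=40, replace=False)
        c = nc.ClusterResult(members, float(vals[members].sum()), 1)
        tf = nc.project_cluster(c, sm, coupling_space, "tf")
        spatial = nc.project_cluster(c, sm, coupling_space, "space")
        # each pair feeds both endpoints: spatial total is twice the tf total
        assert spatial.sum() == pytest.approx(2 * tf.sum())

    def test_unknown_mode_rejected(self, power_space):
        sm = nc.StatMap(np.ones(power_space.n_bins), "t", np.ones(power_space.n_bins), (1, 9))
        c = nc.ClusterResult(np.array([0]), 1.0, 1)
        with pytest.raises(ValueError):
            nc.project_cluster(c, sm, power_space, "volume")
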