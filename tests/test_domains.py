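"""Domain interval resolution, JSD clustering, dynamic tree cut, validation."""

import itertools

import numpy as np
import pytest

from vepcal.domains import (
    DomainInterval,
    assign_variant_to_cluster,
    cluster_and_split,
    cluster_validation,
    grid_search_max_count,
    jsd_matrix,
    resolve_overlaps,
    score_histogram,
)


class TestResolveOverlaps:
    def test_reciprocal_overlap_merges(self):
        out = resolve_overlaps(
            [DomainInterval("G", 1, 100, "a"), DomainInterval("G", 40, 140, "b")]
        )
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1, 140)

    def test_small_overlap_splits_at_midpoint(self):
        out = resolve_overlaps(
            [DomainInterval("G", 1, 100, "a"), DomainInterval("G", 90, 300, "b")]
        )
        assert [(iv.start, iv.end) for iv in out] == [(1, 95), (96, 300)]

    def test_disjoint_unchanged(self):
        ivs = [DomainInterval("G", 1, 50, "a"), DomainInterval("G", 60, 90, "b")]
        assert resolve_overlaps(ivs) == ivs

    def test_result_is_nonoverlapping(self):
        ivs = [
            DomainInterval("G", 1, 80, "a"),
            DomainInterval("G", 40, 120, "b"),
            DomainInterval("G", 115, 300, "c"),
        ]
        out = resolve_overlaps(ivs)
        for x, y in itertools.combinations(out, 2):
            assert min(x.end, y.end) < max(x.start, y.start)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            DomainInterval("G", 10, 5, "bad")


class TestHistogramsAndJSD:
    def test_histogram_sums_to_one(self, rng):
        h = score_histogram(rng.uniform(0, 1, 500))
        assert h.sum() == pytest.approx(1.0)

    def test_uniform_scores_near_flat(self, rng):
        h = score_histogram(rng.uniform(0, 1, 10000), n_bins=20)
        chi2 = np.sum((h - 1 / 20) ** 2 / (1 / 20)) * 10000
        # generous chi-square sanity bound for 19 degrees of freedom
        assert chi2 < 60

    def test_single_score_dominant_bin(self):
        h = score_histogram(np.array([0.505]), n_bins=10)
        assert h.max() > 0.99

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            score_histogram(np.array([]))

    def test_identical_histograms_zero_distance(self, rng):
        h = score_histogram(rng.beta(2, 5, 300))
        assert jsd_matrix([h, h])[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_maximal(self):
        a = np.array([1.0, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 1.0])
        assert jsd_matrix([a, b])[0, 1] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, rng):
        hs = rng.dirichlet(np.ones(5), size=4)
        mat = jsd_matrix(hs)
        for i in range(4):
            for j in range(4):
                p, q = hs[i], hs[j]
                m = (p + q) / 2
                kl = lambda a, b: np.sum(
                    np.where(a > 0, a * np.log2(a / b), 0.0)
                )
                expected = np.sqrt((kl(p, m) + kl(q, m)) / 2)
                assert mat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_triangle_inequality(self, rng):
        hs = rng.dirichlet(np.ones(8), size=6)
        mat = jsd_matrix(hs)
        for i, j, k in itertools.permutations(range(6), 3):
            assert mat[i, k] <= mat[i, j] + mat[j, k] + 1e-12


def block_jsd():
    """Distance matrix of a 4-leaf balanced tree: (0,1) close, (2,3) close."""
    m = np.full((4, 4), 0.8)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = 0.1
    m[2, 3] = m[3, 2] = 0.1
    return m


class TestDynamicCut:
    def test_zero_counts_single_cluster(self):
        labels, flagged = cluster_and_split(block_jsd(), [0, 0, 0, 0], 100)
        assert len(set(labels)) == 1 and not flagged

    def test_max_count_at_total_single_cluster(self):
        labels, _ = cluster_and_split(block_jsd(), [300] * 4, 1200)
        assert len(set(labels)) == 1

    def test_balanced_tree_splits_into_pairs(self):
        labels, flagged = cluster_and_split(block_jsd(), [300] * 4, 650)
        assert len(set(labels)) == 2
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert not flagged

    def test_counts_respect_max_after_split(self, rng):
        n = 12
        d = rng.uniform(0.2, 0.9, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        counts = rng.integers(10, 200, n)
        labels, flagged = cluster_and_split(d, counts, 250)
        for c in set(labels):
            idx = np.nonzero(labels == c)[0]
            if not any(i in flagged for i in idx):
                assert counts[idx].sum() <= 250

    def test_unsplittable_singleton_flagged(self):
        labels, flagged = cluster_and_split(block_jsd(), [900, 10, 10, 10], 500)
        assert 0 in flagged


class TestGridSearch:
    def test_achieves_exact_target_when_possible(self):
        # two natural clusters of 500 each: median 500 achievable
        mc, labels = grid_search_max_count(block_jsd(), [250, 250, 250, 250],
                                           target_median=500)
        counts = [sum([250] * list(labels).count(c))
                  for c in sorted(set(labels))]
        med = np.median([250 * list(labels).count(c) for c in set(labels)])
        assert med == pytest.approx(500)

    def test_large_target_keeps_coarsest(self):
        mc, labels = grid_search_max_count(block_jsd(), [100] * 4,
                                           target_median=10000)
        assert len(set(labels)) == 1

    def test_deterministic(self):
        a = grid_search_max_count(block_jsd(), [250] * 4, 500)
        b = grid_search_max_count(block_jsd(), [250] * 4, 500)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])


class TestClusterValidation:
    def test_cluster_controls_match_better_than_shifted_global(self, rng):
        allv = np.concatenate([rng.beta(2, 8, 500), rng.beta(9, 2, 160)])
        rep = cluster_validation(
            allv,
            cluster_benign_scores=rng.beta(2, 8, 200),
            cluster_pathogenic_scores=rng.beta(9, 2, 100),
            global_benign_scores=rng.beta(4, 4, 200),
            global_pathogenic_scores=rng.beta(4, 4, 200),
            seed=0,
        )
        assert rep["difference"] > 0

    def test_identical_controls_near_zero_difference(self, rng):
        allv = np.concatenate([rng.beta(2, 8, 400), rng.beta(9, 2, 120)])
        ben = rng.beta(2, 8, 150)
        path = rng.beta(9, 2, 80)
        rep = cluster_validation(allv, ben, path, ben, path, seed=1)
        assert rep["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_components_ordered_by_mean(self, rng):
        allv = np.concatenate([rng.beta(2, 8, 400), rng.beta(9, 2, 200)])
        rep = cluster_validation(allv, rng.beta(2, 8, 100), rng.beta(9, 2, 100),
                                 rng.beta(4, 4, 100), rng.beta(4, 4, 100),
                                 seed=2)
        # benign JSD is against the lower-mean component: a left-shifted
        # benign set should match it far better than the pathogenic one does
        assert rep["jsd_benign_cluster"] < rep["jsd_pathogenic_global"]

    def test_too_few_scores(self, rng):
        with pytest.raises(ValueError):
            cluster_validation(rng.uniform(0, 1, 10), [], [], [], [])


class TestAssignment:
    @pytest.fixture()
    def setup(self):
        domains = [
            DomainInterval("G", 10, 50, "d1"),
            DomainInterval("G", 60, 90, "d2"),
        ]
        clusters = {"d1": 0, "d2": 1}
        return domains, clusters

    def test_inside_interval(self, setup):
        domains, clusters = setup
        assert assign_variant_to_cluster("G", 30, domains, clusters) == 0

    def test_boundaries_inclusive(self, setup):
        domains, clusters = setup
        assert assign_variant_to_cluster("G", 10, domains, clusters) == 0
        assert assign_variant_to_cluster("G", 50, domains, clusters) == 0
        assert assign_variant_to_cluster("G", 60, domains, clusters) == 1

    def test_outside_and_missing(self, setup):
        domains, clusters = setup
        assert assign_variant_to_cluster("G", 55, domains, clusters) == "non_domain"
        assert assign_variant_to_cluster("G", None, domains, clusters) == "non_domain"
        assert assign_variant_to_cluster("X", 30, domains, clusters) == "non_domain"
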