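import itertools

import numpy as np
import pytest

import sfnull as sf

from conftest import make_table


def line_table(positions, networks=None):
    return make_table(np.asarray(positions, float)[:, None], networks=networks)


class TestCenterSampling:
    def test_radius_zero_admits_any_distinct_centers(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(size=(60, 3)) * 50)
        centers = sf.sample_cluster_centers(table, 0.0, 34, seed=1)
        assert len(set(centers)) == 34
        from scipy.spatial.distance import pdist

        coords = table.coords[table.indices_of(list(centers))]
        assert len(pdist(coords)) == 34 * 33 // 2 == 561

    def test_spacing_constraint_is_strict(self):
        table = line_table(np.arange(10) * 10.0)
        for seed in range(30):
            centers = sf.sample_cluster_centers(table, 6.0, 3, seed=seed)
            pos = sorted(table.coords[table.indices_of(list(centers)), 0])
            gaps = np.diff(pos)
            assert (gaps > 12.0).all()

    def test_distribution_matches_sequential_process_oracle(self):
        """Empirical center-set frequencies against an exact recursion over
        the sequential placement process (uniform over unblocked candidates,
        restart on dead ends)."""
        positions = np.arange(10) * 10.0
        table = line_table(positions)

        def blocked(i, j):
            return abs(positions[i] - positions[j]) <= 12.0

        def recurse(chosen, available):
            if len(chosen) == 3:
                return {frozenset(chosen): 1.0}
            if not available:
                return {"dead": 1.0}
            out = {}
            p = 1.0 / len(available)
            for c in available:
                rest = [a for a in available if a != c and not blocked(a, c)]
                for key, prob in recurse(chosen + [c], rest).items():
                    out[key] = out.get(key, 0.0) + p * prob
            return out

        dist = recurse([], list(range(10)))
        dead = dist.pop("dead", 0.0)
        exact = {k: v / (1 - dead) for k, v in dist.items()}

        counts = {}
        n_draws = 4000
        rng = np.random.default_rng(5)
        for _ in range(n_draws):
            ids = sf.sample_cluster_centers(table, 6.0, 3, rng=rng)
            key = frozenset(int(s[1:]) for s in ids)
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(
            abs(exact.get(k, 0.0) - counts.get(k, 0) / n_draws)
            for k in set(exact) | set(counts)
        )
        assert tv < 0.05

    def test_zcn_never_uses_rsfmri_centers(self):
        rng = np.random.default_rng(1)
        networks = np.zeros(30, dtype=int)
        networks[7] = 4
        table = make_table(rng.normal(size=(30, 3)) * 60, networks=networks)
        for seed in range(200):
            centers = sf.sample_cluster_centers(table, 1.0, 5, "Z-cn", seed=seed)
            assert "s7" not in set(centers)

    def test_packing_failure_reports_progress(self):
        table = line_table(np.arange(5) * 10.0)
        with pytest.raises(sf.PackingError) as exc:
            sf.sample_cluster_centers(table, 30.0, 3, seed=0, max_proposals=200)
        assert exc.value.placed < 3
        assert exc.value.requested == 3


class TestClusters:
    def test_isolated_center_forms_singleton_cluster(self):
        table = line_table([0.0, 7.0, 14.0])
        clusters = sf.build_clusters(np.array(["s0"], dtype=object), 6.0, table)
        assert list(clusters.members[0]) == ["s0"]

    def test_membership_matches_bruteforce_distance_filter(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.normal(size=(40, 3)) * 30)
        centers = sf.sample_cluster_centers(table, 8.0, 3, seed=3)
        clusters = sf.build_clusters(centers, 8.0, table)
        cidx = table.indices_of(list(centers))
        for c, members in zip(cidx, clusters.members):
            d = np.linalg.norm(table.coords - table.coords[c], axis=1)
            expected = set(table.sample_ids[d <= 8.0])
            assert set(members) == expected

    def test_omit_rs_excludes_rsfmri_members(self):
        networks = np.array([0, 2, 0])
        table = line_table([0.0, 3.0, 20.0], networks=networks)
        clusters = sf.build_clusters(
            np.array(["s0"], dtype=object), 6.0, table, variant="omit-RS"
        )
        # the rsfMRI sample 3 mm away is not eligible pool material
        assert list(clusters.members[0]) == ["s0"]


class TestGrouping:
    def test_partition_uses_each_cluster_once(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.normal(size=(120, 3)) * 60)
        nets, clusters = sf.simulate_network_set(table, 5.0, seed=8)
        assert nets.n_networks == 13
        assert sorted(nets.composition) == sorted(sf.DEFAULT_COMPOSITION)
        all_members = np.concatenate(nets.networks)
        assert len(all_members) == len(set(all_members))
        assert set(all_members) == set(np.concatenate(clusters.members))

    def test_three_singleton_partitions_are_uniform(self):
        table = line_table([0.0, 40.0, 80.0])
        clusters = sf.build_clusters(
            np.array(["s0", "s1", "s2"], dtype=object), 6.0, table
        )
        counts = {}
        rng = np.random.default_rng(6)
        n = 3000
        for _ in range(n):
            nets = sf.group_into_networks(clusters, (2, 1), rng=rng)
            key = frozenset(nets.networks[0])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 0.03

    def test_same_seed_reproduces_grouping(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.normal(size=(100, 3)) * 60)
        a, _ = sf.simulate_network_set(table, 6.0, seed=12)
        b, _ = sf.simulate_network_set(table, 6.0, seed=12)
        for x, y in zip(a.networks, b.networks):
            np.testing.assert_array_equal(x, y)

    def test_composition_mismatch_is_a_configuration_error(self):
        table = line_table([0.0, 40.0, 80.0])
        clusters = sf.build_clusters(
            np.array(["s0", "s1"], dtype=object), 6.0, table
        )
        with pytest.raises(sf.ConfigurationError):
            sf.group_into_networks(clusters, (2, 1), seed=0)


class TestMetrics:
    def test_single_edge_network(self):
        table = line_table([0.0, 3.0, 50.0])
        clusters = sf.ClusterSet(
            np.array(["s0"], dtype=object), 1.5, [np.array(["s0", "s1"], dtype=object)]
        )
        nets = sf.SimulatedNetworkSet(
            [np.array(["s0", "s1"], dtype=object)], (1,), 1.5, "All"
        )
        m = sf.network_metrics(nets, clusters, table)
        assert m.W == 2
        assert m.median_within_edge_mm == pytest.approx(3.0)

    def test_metrics_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        table = make_table(rng.normal(size=(50, 3)) * 40)
        nets, clusters = sf.simulate_network_set(
            table, 10.0, n_clusters=4, composition=(2, 1, 1), seed=14
        )
        m = sf.network_metrics(nets, clusters, table)
        within = []
        for net in nets.networks:
            coords = table.coords[table.indices_of(list(net))]
            for i, j in itertools.combinations(range(len(coords)), 2):
                within.append(np.linalg.norm(coords[i] - coords[j]))
        centers = table.coords[table.indices_of(list(clusters.center_ids))]
        centerd = [
            np.linalg.norm(centers[i] - centers[j])
            for i, j in itertools.combinations(range(len(centers)), 2)
        ]
        assert m.W == sum(len(n) for n in nets.networks)
        assert m.median_within_edge_mm == pytest.approx(np.median(within))
        assert m.median_center_edge_mm == pytest.approx(np.median(centerd))

    def test_center_distances_do_not_depend_on_radius(self):
        """Cluster size does not affect distances between cluster centers:
        for a fixed center configuration the center-pair median is radius
        invariant."""
        rng = np.random.default_rng(10)
        table = make_table(rng.normal(size=(80, 3)) * 60)
        centers = sf.sample_cluster_centers(table, 12.0, 4, seed=2)
        medians = []
        for radius in (2.0, 6.0, 12.0):
            clusters = sf.build_clusters(centers, radius, table)
            nets = sf.group_into_networks(clusters, (2, 1, 1), seed=3)
            medians.append(sf.network_metrics(nets, clusters, table).median_center_edge_mm)
        assert medians[0] == medians[1] == medians[2]

    def test_w_grows_with_radius_on_average(self, cortex_structured):
        _, table, _ = cortex_structured
        means = []
        for radius in (6.0, 14.0):
            ws = []
            for seed in range(15):
                nets, _ = sf.simulate_network_set(table, radius, seed=seed)
                ws.append(nets.total_samples)
            means.append(np.mean(ws))
        assert means[1] > means[0]


class TestRealNetworkCentroids:
    def test_k_one_returns_coordinate_mean(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(8, 3)) * 10
        table = make_table(coords, networks=np.full(8, 3))
        centroids, _ = sf.real_network_centroids(table, {3: 1})
        np.testing.assert_allclose(centroids[0], coords.mean(axis=0))

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(12)
        blob_a = rng.normal(scale=2.0, size=(10, 3))
        blob_b = rng.normal(scale=2.0, size=(10, 3)) + np.array([20.0, 0, 0])
        coords = np.vstack([blob_a, blob_b])
        table = make_table(coords, networks=np.full(20, 1))
        centroids, median_d = sf.real_network_centroids(table, {1: 2})
        got = sorted(centroids.tolist())
        want = sorted([blob_a.mean(axis=0).tolist(), blob_b.mean(axis=0).tolist()])
        np.testing.assert_allclose(got, want, atol=1.0)
        assert median_d == pytest.approx(np.linalg.norm(centroids[0] - centroids[1]))

    def test_size_ranked_cluster_allocation(self, cortex_structured):
        _, table, _ = cortex_structured
        ks = sf.default_k_per_network(table)
        assert sorted(ks.values()) == [1] + [2] * 3 + [3] * 9
        sizes = {k: int((table.network_labels == k).sum()) for k in ks}
        # larger networks never get fewer clusters than smaller ones
        for a in ks:
            for b in ks:
                if sizes[a] > sizes[b]:
                    assert ks[a] >= ks[b]
        centroids, median_d = sf.real_network_centroids(table)
        assert centroids.shape == (34, 3)
        assert median_d > 0

    def test_undersized_network_is_an_error(self):
        table = make_table([[0, 0, 0], [5, 0, 0]], networks=[1, 1])
        with pytest.raises(sf.ValidationError):
            sf.real_network_centroids(table, {1: 3})
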