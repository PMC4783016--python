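"""Network construction, abundance-weighted peeling, refinement, and pipeline."""
import numpy as np
import pytest

from otunet import (
    MockCommunitySpec,
    NWParams,
    RunConfig,
    SequenceRecord,
    build_network,
    cluster_dataset,
    generate_mock_community,
    peel_clusters,
    refine,
    select_seed,
    verify_membership_structure,
    weighted_degree,
)
from otunet.clustering import Cluster, ClusteringResult, SequenceNetwork
from otunet.scheduler import DistanceEdge


def net_from(pairs, n):
    return build_network([DistanceEdge(i, j, 0.0) for i, j in pairs], n)


class TestBuildNetwork:
    def test_degrees(self):
        net = net_from([(0, 1), (1, 2)], 4)
        assert [net.degree(u) for u in range(4)] == [1, 2, 1, 0]

    def test_empty_edge_list_keeps_all_isolated(self):
        net = net_from([], 3)
        assert all(net.degree(u) == 0 for u in range(3))

    def test_duplicate_edges_collapse(self):
        net = net_from([(0, 1), (0, 1)], 2)
        assert net.degree(0) == 1

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            net_from([(1, 1)], 3)


class TestWeightedDegree:
    def test_star_center_with_unit_abundances(self):
        net = net_from([(0, 1), (0, 2), (0, 3)], 4)
        assert weighted_degree(net, 0, [1, 1, 1, 1]) == 3

    def test_isolated_node_counts_only_its_duplicates(self):
        net = net_from([], 1)
        assert weighted_degree(net, 0, [5]) == 4

    def test_neighbor_abundances_plus_own_duplicates(self):
        net = net_from([(0, 1), (0, 2)], 3)
        assert weighted_degree(net, 0, [2, 2, 3]) == 2 + 3 + 1

    def test_inactive_node_rejected(self):
        net = net_from([(0, 1)], 2)
        net.active.discard(0)
        with pytest.raises(ValueError):
            weighted_degree(net, 0, [1, 1])


class TestSelectSeed:
    def test_star_center_wins(self):
        net = net_from([(2, 0), (2, 1), (2, 3), (2, 4)], 5)
        assert select_seed(net, [1] * 5) == 2

    def test_tie_broken_by_smallest_index(self):
        net = net_from([(0, 1), (2, 3)], 4)
        assert select_seed(net, [1, 1, 1, 1]) == 0

    def test_heavily_duplicated_leaf_beats_small_hub(self):
        # hub 0 with three unit leaves (wd 3); leaf 4 with abundance 10 (wd 10)
        net = net_from([(0, 1), (0, 2), (0, 3), (4, 5)], 6)
        abundance = [1, 1, 1, 1, 10, 1]
        assert weighted_degree(net, 4, abundance) == 10
        assert select_seed(net, abundance) == 4

    def test_no_active_nodes_rejected(self):
        net = net_from([], 2)
        net.active = set()
        with pytest.raises(ValueError):
            select_seed(net, [1, 1])


class TestPeelClusters:
    def test_two_disjoint_stars(self):
        net = net_from([(0, 1), (0, 2), (0, 3), (4, 5), (4, 6), (4, 7)], 8)
        result, singletons = peel_clusters(net, [1] * 8)
        member_sets = sorted(
            (sorted(c.members) for c in result.clusters), key=lambda m: m[0]
        )
        assert member_sets == [[0, 1, 2, 3], [4, 5, 6, 7]]
        assert singletons == set()

    def test_path_peels_at_the_middle(self):
        net = net_from([(0, 1), (1, 2)], 3)
        result, singletons = peel_clusters(net, [1, 1, 1])
        assert result.clusters[0].seed == 1
        assert result.clusters[0].members == {0, 1, 2}
        assert singletons == set()

    def test_edgeless_network_yields_only_singletons(self):
        net = net_from([], 4)
        result, singletons = peel_clusters(net, [1] * 4)
        assert singletons == {0, 1, 2, 3}
        assert all(len(c.members) == 1 for c in result.clusters)
        assert len(result.clusters) == 4

    def test_partition_covers_every_node(self):
        rng = np.random.default_rng(3)
        n = 40
        pairs = {
            (int(a), int(b))
            for a, b in rng.integers(0, n, size=(80, 2))
            if a != b
        }
        net = net_from([(min(a, b), max(a, b)) for a, b in pairs], n)
        abundance = rng.integers(1, 5, size=n).tolist()
        result, _ = peel_clusters(net, abundance)
        seen = sorted(u for c in result.clusters for u in c.members)
        assert seen == list(range(n))


def mutate_at(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1 :]


class TestRefine:
    def toy(self):
        rng = np.random.default_rng(11)
        s1 = "".join(rng.choice(list("ACGT"), 100))
        s2 = mutate_at(s1, 50, "A" if s1[50] != "A" else "C")  # 1% away from s1
        l1 = mutate_at(s1, 10, "A" if s1[10] != "A" else "C")
        l2 = mutate_at(s2, 90, "A" if s2[90] != "A" else "C")
        uniques = [SequenceRecord(f"u{i}", s) for i, s in enumerate([s1, s2, l1, l2])]
        initial_net = net_from([(0, 2), (1, 3)], 4)
        initial = ClusteringResult(
            [Cluster(seed=0, members={0, 2}), Cluster(seed=1, members={1, 3})]
        )
        return uniques, initial_net, initial

    def test_seeds_within_threshold_merge_with_their_stars(self):
        uniques, initial_net, initial = self.toy()
        final = refine(
            initial, set(), uniques, [1] * 4, 0.03, NWParams(), initial_net
        )
        assert len(final.clusters) == 1
        assert final.clusters[0].members == {0, 1, 2, 3}

    def test_distant_seeds_leave_initial_clusters_unchanged(self):
        uniques, initial_net, initial = self.toy()
        final = refine(
            initial, set(), uniques, [1] * 4, 0.001, NWParams(), initial_net
        )
        sets = sorted(sorted(c.members) for c in final.clusters)
        assert sets == [[0, 2], [1, 3]]

    def test_singleton_within_threshold_is_absorbed(self):
        uniques, initial_net, initial = self.toy()
        # node 3 now a singleton instead of a star member
        initial_net = net_from([(0, 2)], 4)
        initial = ClusteringResult(
            [
                Cluster(seed=0, members={0, 2}),
                Cluster(seed=1, members={1}),
                Cluster(seed=3, members={3}),
            ]
        )
        final = refine(
            initial, {3}, uniques, [1] * 4, 0.03, NWParams(), initial_net
        )
        assert len(final.clusters) == 1
        assert final.clusters[0].members == {0, 1, 2, 3}


class TestClusterDataset:
    def test_recovers_planted_strains(self):
        readset = generate_mock_community(
            MockCommunitySpec(
                n_strains=3, reads_per_strain=20, center_length=250, rng_seed=5
            )
        )
        run = cluster_dataset(readset.records, RunConfig(sample_size=30, workers=1))
        assert run.n_otus == 3
        assignment = run.assignment()
        by_otu = {}
        for rid, otu in assignment.items():
            by_otu.setdefault(otu, set()).add(readset.truth[rid])
        assert all(len(strains) == 1 for strains in by_otu.values())

    def test_identical_reads_collapse_to_one_full_otu(self):
        records = [SequenceRecord(f"r{i}", "ACGTACGTAA" * 5) for i in range(12)]
        run = cluster_dataset(records, RunConfig(workers=1))
        assert run.n_otus == 1
        assert run.otus[0].size == 12

    def test_two_distant_reads_stay_apart(self):
        records = [
            SequenceRecord("r1", "ACGT" * 20),
            SequenceRecord("r2", "TTGG" * 20),
        ]
        run = cluster_dataset(
            records, RunConfig(kmer_threshold=0.5, workers=1)
        )
        assert run.n_otus == 2
        assert all(o.size == 1 for o in run.otus)

    def test_membership_structure_holds_on_frozen_run(self, frozen_run):
        assert verify_membership_structure(frozen_run)

    def test_every_read_lands_in_exactly_one_otu(self, frozen_community, frozen_run):
        out_ids = sorted(rid for o in frozen_run.otus for rid in o.member_ids)
        assert out_ids == sorted(r.id for r in frozen_community.records)
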