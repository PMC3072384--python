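"""Decision tree construction and hierarchical 5-NN classification."""

import numpy as np
import pytest

from breedtrace import (
    BreedTreeSpec,
    TreeConfig,
    build_tree,
    classify_sample,
    cluster_breeds_at_node,
    filter_missing,
    knn_vote,
    simulate_dataset,
    two_level_spec,
)
from breedtrace.pca import PCCoordinates
from breedtrace.tree import PAPER_NODE_K, PAPER_P1_SIZES, PAPER_TOPOLOGY


def coords_of(points):
    pts = np.asarray(points, dtype=float)
    return PCCoordinates(pts.reshape(len(pts), -1), [f"s{i}" for i in range(len(pts))])


class TestKnnVote:
    def vote(self, child_labels, breeds=None, test_breed="x"):
        n = len(child_labels)
        coords = np.arange(n, dtype=float).reshape(-1, 1)
        return knn_vote(
            np.array([0.0]), coords, [f"s{i}" for i in range(n)],
            child_labels, breeds or child_labels, test_breed=test_breed,
        )

    def test_three_of_five_majority_assigns(self):
        assert self.vote(["A", "A", "A", "B", "B"]).predicted == "A"

    def test_no_majority_unassigned(self):
        assert self.vote(["A", "A", "B", "B", "C"]).predicted == "unassigned"

    def test_all_neighbors_same_breed_counts_five(self):
        d = self.vote(["A"] * 5, breeds=["x"] * 5, test_breed="x")
        assert d.n_correct_breed == 5

    def test_distances_non_decreasing(self):
        d = self.vote(["A", "B", "A", "B", "A", "B"])
        assert (np.diff(d.neighbor_dists) >= 0).all()

    def test_distance_ties_broken_by_sample_id(self):
        coords = np.zeros((6, 1))
        d = knn_vote(np.array([0.0]), coords, ["s5", "s4", "s3", "s2", "s1", "s0"],
                     ["A"] * 6, ["A"] * 6, test_breed="A")
        assert d.neighbor_ids.tolist() == ["s0", "s1", "s2", "s3", "s4"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            knn_vote(np.array([0.0]), np.empty((0, 1)), [], [], [])


class TestClusterBreeds:
    def test_separable_two_breeds(self):
        pts = [[-5.0], [-4.9], [-5.1], [5.0], [4.9], [5.1]]
        labels = ["a", "a", "a", "b", "b", "b"]
        partition, purity = cluster_breeds_at_node(coords_of(pts), labels, 2, seed=0)
        assert sorted(partition) == [("a",), ("b",)]
        assert purity == {"a": 1.0, "b": 1.0}

    def test_identical_coordinates_rejected(self):
        pts = [[1.0]] * 6
        with pytest.raises(ValueError, match="distinct"):
            cluster_breeds_at_node(coords_of(pts), ["a", "a", "a", "b", "b", "b"], 2)

    def test_close_pair_groups_against_outgroup(self):
        """Two weakly diverged breeds cluster together versus a distant one."""
        spec = BreedTreeSpec(
            nodes={"pair": ["p1", "p2"], "far": None},
            branch_fst={"pair": 0.2, "p1": 0.02, "p2": 0.02, "far": 0.2},
            n_per_breed=20, n_snps=400, missing_rate=0.02, seed=3,
        )
        gm, _ = simulate_dataset(spec)
        gm = filter_missing(gm)
        from breedtrace.encoding import center_impute
        from breedtrace.pca import fit_pca

        X, means = center_impute(gm)
        _, coords = fit_pca(X, 2, gm.snp_ids, means, gm.sample_ids)
        partition, _ = cluster_breeds_at_node(coords, gm.labels.to_numpy(dtype=str), 2, seed=0)
        assert ("p1", "p2") in partition


class TestBuildTree:
    def test_two_breeds_gives_two_leaves(self):
        gm, _ = simulate_dataset(BreedTreeSpec(nodes={"a": None, "b": None}, branch_fst=0.3,
                                               n_per_breed=15, n_snps=300, seed=1))
        tree = build_tree(filter_missing(gm), TreeConfig(seed=1, build_panels=False))
        assert len(tree.children) == 2
        assert all(c.is_leaf for c in tree.children)

    def test_children_partition_breeds(self, small_sim):
        gm, _ = small_sim
        tree = build_tree(filter_missing(gm), TreeConfig(seed=11, build_panels=False))
        for node in tree.iter_nodes():
            if not node.is_leaf:
                got = sorted(b for c in node.children for b in c.breeds)
                assert got == sorted(node.breeds)

    def test_single_breed_rejected(self):
        gm, _ = simulate_dataset(BreedTreeSpec(nodes={"a": None, "b": None}, branch_fst=0.2,
                                               n_per_breed=10, n_snps=100, seed=2))
        only = gm.restrict_samples(np.asarray(gm.labels == "a"))
        with pytest.raises(ValueError, match="2 breeds"):
            build_tree(only, TreeConfig(seed=0))

    def test_reference_topology_replay_has_19_leaves(self):
        """The bundled 19-breed worldwide cattle hierarchy replays exactly."""
        breeds = sorted(
            b for b in _topo_leaves(PAPER_TOPOLOGY["World"])
        )
        assert len(breeds) == 19
        spec = BreedTreeSpec(nodes=PAPER_TOPOLOGY["World"], branch_fst=0.12,
                             n_per_breed=6, n_snps=1500, missing_rate=0.03, seed=5)
        gm, _ = simulate_dataset(spec)
        gm = filter_missing(gm)
        cfg = TreeConfig.paper_preset(seed=5)
        tree = build_tree(gm, cfg)
        names = {n.name for n in tree.iter_nodes() if not n.is_leaf}
        assert names == set(PAPER_NODE_K)
        leaves = [n.name for n in tree.iter_nodes() if n.is_leaf]
        assert len(leaves) == 19
        for node in tree.iter_nodes():
            if not node.is_leaf:
                assert node.k == PAPER_NODE_K[node.name]
                p1 = PAPER_P1_SIZES[node.name]
                assert node.panel.tier_sizes == (p1, 2 * p1, 3 * p1)

    def test_training_individuals_reach_their_breed_leaf(self):
        """Strong differentiation: every sample descends to its own breed."""
        gm, _ = simulate_dataset(two_level_spec(between_fst=0.3, within_fst=0.2,
                                                n_per_breed=15, n_snps=400, seed=6,
                                                missing_rate=0.02, redundancy_factor=2))
        gm = filter_missing(gm)
        tree = build_tree(gm, TreeConfig(seed=6, p1_size=15, n_top=100))
        wrong = 0
        for i in range(gm.n_samples):
            r = classify_sample(tree, gm.values[i], gm.missing[i], gm.snp_ids, mode="full")
            wrong += r.final != gm.labels.iloc[i]
        assert wrong == 0

    def test_classification_path_consistent_with_topology(self, small_sim):
        gm, _ = small_sim
        gmf = filter_missing(gm)
        tree = build_tree(gmf, TreeConfig(seed=11, p1_size=20, n_top=100))
        r = classify_sample(tree, gm.values[0], gm.missing[0], gm.snp_ids, mode="P2")
        node = tree
        for d in r.decisions:
            assert d.node == node.name
            if d.predicted == "unassigned":
                assert d is r.decisions[-1]
                assert r.final == "unassigned"
                return
            node = node.child_named(d.predicted)
        assert r.final in node.breeds

    def test_classification_deterministic(self, small_sim):
        gm, _ = small_sim
        gmf = filter_missing(gm)
        tree = build_tree(gmf, TreeConfig(seed=11, build_panels=False))
        r1 = classify_sample(tree, gm.values[5], gm.missing[5], gm.snp_ids)
        r2 = classify_sample(tree, gm.values[5], gm.missing[5], gm.snp_ids)
        assert r1.final == r2.final
        assert [d.predicted for d in r1.decisions] == [d.predicted for d in r2.decisions]


def _topo_leaves(sub):
    out = []
    for name, s in sub.items():
        if s is None:
            out.append(name)
        elif isinstance(s, dict):
            out.extend(_topo_leaves(s))
        else:
            out.extend(s)
    return out
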