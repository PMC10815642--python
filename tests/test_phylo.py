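"""Neighbor joining against closed forms, additive recovery, the
exhaustive least-squares oracle, bootstrap behaviour and rooting."""

import numpy as np
import pytest

from conftest import (
    graph_bipartitions,
    graph_distance_matrix,
    least_squares_topology,
    random_additive_graph,
)

from mhcdiv.distance import DistanceMatrix, pairwise_matrix
from mhcdiv.phylo import (
    bipartitions,
    bootstrap_support,
    nj,
    read_newick,
    root_on_outgroup,
    write_newick,
)


def additive_case(n, seed):
    rng = np.random.default_rng(seed)
    g = random_additive_graph(n, rng)
    labels = [f"t{i}" for i in range(n)]
    D = graph_distance_matrix(g, n)
    scale = 99.0 / D.max()  # keep within the percent-difference domain
    return labels, D * scale, graph_bipartitions(g, labels)


def tree_path_lengths(tree):
    """Leaf-to-leaf path lengths from the built tree (oracle-free check
    of branch-length recovery)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n = len(labels)
    D = np.zeros((n, n))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.distance(tx[a], tx[b])
    return labels, D


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_additive_matrix_recovered_exactly(self, n):
        labels, D, true_biparts = additive_case(n, seed=100 + n)
        tree = nj(DistanceMatrix(labels, D))
        assert bipartitions(tree) == true_biparts
        tl, TD = tree_path_lengths(tree)
        order = [tl.index(l) for l in labels]
        assert np.allclose(TD[np.ix_(order, order)], D, atol=1e-9)

    def test_agrees_with_least_squares_search_n5(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            g = random_additive_graph(5, rng)
            D = graph_distance_matrix(g, 5)
            labels = [str(i) for i in range(5)]
            tree = nj(DistanceMatrix(labels, D * (99.0 / D.max())))
            assert bipartitions(tree) == least_squares_topology(D)

    def test_leaf_order_permutation_invariance(self, rng):
        labels, D, _ = additive_case(6, seed=42)
        perm = rng.permutation(6)
        dm1 = DistanceMatrix(labels, D)
        dm2 = DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)])
        assert bipartitions(nj(dm1)) == bipartitions(nj(dm2))

    def test_ultrametric_distances_reproduced(self):
        # balanced clock tree: ((A:1,B:1):1,(C:1,D:1):1) as a distance matrix
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        tree = nj(DistanceMatrix(list("ABCD"), D))
        tl, TD = tree_path_lengths(tree)
        order = [tl.index(l) for l in "ABCD"]
        assert np.allclose(TD[np.ix_(order, order)], D, atol=1e-9)

    def test_rejects_tiny_or_negative(self):
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestBootstrap:
    @staticmethod
    def two_clade_alignment(n_central=200, n_within=100):
        """Two 3-leaf clades with diagnostic columns for every internal
        edge: the central split and the (a1,a2) and (b1,b2) cherries."""
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        cols = (
            [list("AAACCC")] * n_central
            + [list("GGTTTT")] * n_within
            + [list("TTTGGT")] * n_within
        )
        seqs = ["".join(c[i] for c in cols) for i in range(6)]
        return labels, seqs

    @staticmethod
    def noisy_alignment(n_cols=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(6)]
        seqs = ["".join(rng.choice(list("ACGT"), n_cols)) for _ in range(6)]
        return labels, seqs

    @staticmethod
    def dist_fn(labels, seqs):
        return pairwise_matrix(list(labels), list(seqs), level="nt")

    def test_diagnostic_clades_get_full_support(self):
        labels, seqs = self.two_clade_alignment()
        res = bootstrap_support(labels, seqs, self.dist_fn, n_reps=200, seed=5)
        assert len(res.supports) == 3
        assert all(s == 100.0 for s in res.supports.values())

    def test_single_replicate_supports_are_binary(self):
        labels, seqs = self.noisy_alignment()
        res = bootstrap_support(labels, seqs, self.dist_fn, n_reps=1, seed=2)
        assert set(res.supports.values()) <= {0.0, 100.0}

    def test_seeded_reproducibility(self):
        labels, seqs = self.noisy_alignment(seed=3)
        r1 = bootstrap_support(labels, seqs, self.dist_fn, n_reps=50, seed=77)
        r2 = bootstrap_support(labels, seqs, self.dist_fn, n_reps=50, seed=77)
        assert r1.supports == r2.supports
        assert write_newick(r1.tree) == write_newick(r2.tree)

    def test_degenerate_replicates_skipped_and_counted(self):
        # one variable column only: most resamples are all-constant
        labels = ["a", "b", "c", "d"]
        seqs = ["AAAA", "AAAA", "AAAC", "AAAC"]
        res = bootstrap_support(labels, seqs, self.dist_fn, n_reps=50, seed=1)
        assert 0 < res.n_skipped < res.n_replicates
        # supports are percentages of the non-degenerate replicates
        assert all(0.0 <= s <= 100.0 for s in res.supports.values())


class TestRooting:
    def test_three_taxon_rooting(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = root_on_outgroup(nj(dm), "C")
        assert tree.is_rooted
        root_children = tree.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in c.leaf_iter()) for c in root_children]
        assert sorted(map(tuple, sides)) == [("A", "B"), ("C",)]

    def test_rooting_preserves_bipartitions(self):
        labels, D, true_biparts = additive_case(6, seed=9)
        tree = nj(DistanceMatrix(labels, D))
        before = bipartitions(tree)
        root_on_outgroup(tree, labels[0])
        assert bipartitions(tree) == before == true_biparts

    def test_missing_outgroup(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        with pytest.raises(KeyError):
            root_on_outgroup(nj(dm), "Z")


class TestNewick:
    def test_roundtrip_topology_lengths_supports(self):
        labels, D, _ = additive_case(6, seed=33)
        tree = nj(DistanceMatrix(labels, D))
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node is not tree.seed_node:
                node.label = "87"
        text = write_newick(tree)
        back = read_newick(text)
        assert bipartitions(back) == bipartitions(tree)
        assert "87" in text
        tl1, D1 = tree_path_lengths(tree)
        tl2, D2 = tree_path_lengths(back)
        order = [tl2.index(l) for l in tl1]
        assert np.allclose(D2[np.ix_(order, order)], D1, atol=1e-6)
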