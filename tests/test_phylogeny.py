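import io

import dendropy
import numpy as np
import pytest

from metpathcomp.evosim import simulate_tree
from metpathcomp.pathway_io import ValidationError
from metpathcomp.phylogeny import (
    DissimilarityMatrix,
    SimilarityMatrix,
    as_newick,
    collapse_stack,
    neighbor_joining,
    robinson_foulds,
    to_dissimilarity,
    tree_distance_matrix,
)
from metpathcomp.weighting import WeightedPage


def wpage(organisms, matrix, weight=1.0, pathway="p"):
    return WeightedPage(pathway, tuple(organisms), np.asarray(matrix, float),
                        weight)


class TestCollapse:
    def test_single_zero_page(self):
        sim = collapse_stack([wpage(("O1", "O2"), np.zeros((2, 2)))])
        assert np.array_equal(sim.matrix, np.zeros((2, 2)))

    def test_additivity(self):
        p1 = wpage(("O1", "O2"), [[0, 2], [2, 0]], 2)
        p2 = wpage(("O1", "O2"), [[0, 3], [3, 0]], 3)
        sim = collapse_stack([p1, p2])
        assert sim.matrix[0, 1] == 5.0

    def test_matches_manual_resummation(self, rng):
        for _ in range(50):
            n, m = 4, int(rng.integers(1, 6))
            pages = []
            for k in range(m):
                w = float(rng.integers(0, 4))
                adj = rng.random((n, n)) < 0.5
                adj = adj | adj.T
                pages.append(wpage([f"O{i}" for i in range(n)],
                                   np.where(adj, w, 0.0), w, f"p{k}"))
            sim = collapse_stack(pages)
            manual = np.zeros((n, n))
            for p in pages:
                manual += p.matrix
            assert np.array_equal(sim.matrix, manual)

    def test_order_mismatch_rejected(self):
        p1 = wpage(("O1", "O2"), np.zeros((2, 2)))
        p2 = wpage(("O2", "O1"), np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            collapse_stack([p1, p2])


class TestToDissimilarity:
    def test_direct_subtraction(self):
        sim = SimilarityMatrix(("A", "B"), np.array([[5.0, 2.0], [2.0, 5.0]]))
        d = to_dissimilarity(sim)
        assert np.array_equal(d.matrix, np.array([[0.0, 3.0], [3.0, 0.0]]))

    def test_constant_matrix_gives_zero(self):
        sim = SimilarityMatrix(("A", "B"), np.full((2, 2), 4.0))
        assert np.array_equal(to_dissimilarity(sim).matrix, np.zeros((2, 2)))

    def test_unequal_diagonal_forced_to_zero(self, caplog):
        # with b=false the self-similarity can differ between organisms
        sim = SimilarityMatrix(("A", "B"), np.array([[5.0, 2.0], [2.0, 4.0]]))
        with caplog.at_level("WARNING"):
            d = to_dissimilarity(sim)
        assert np.array_equal(d.matrix, np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert any("self-dissimilarity" in r.message for r in caplog.records)

    def test_order_reversing(self, rng):
        m = rng.random((4, 4)) * 10
        m = (m + m.T) / 2
        np.fill_diagonal(m, m.max() + 1)
        sim = SimilarityMatrix(tuple("ABCD"), m)
        d = to_dissimilarity(sim).matrix
        iu = np.triu_indices(4, 1)
        for a in zip(*iu):
            for b in zip(*iu):
                assert (m[a] >= m[b]) == (d[a] <= d[b])


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # distances measured on the tree ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DissimilarityMatrix(ids, D))
        truth = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:4):0);",
                                  schema="newick")
        assert robinson_foulds(tree, truth) == 0
        recovered = tree_distance_matrix(tree, ids)
        assert np.allclose(recovered, D, atol=1e-12)

    def test_three_taxon_branch_lengths(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(DissimilarityMatrix(("A", "B", "C"), D))
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_exact_on_random_additive_matrices(self):
        for seed in range(12):
            n = 4 + seed % 9  # up to 12 taxa
            truth = simulate_tree(n, seed)
            ids = tuple(f"O{i+1}" for i in range(n))
            D = tree_distance_matrix(truth, ids)
            tree = neighbor_joining(DissimilarityMatrix(ids, D))
            assert robinson_foulds(tree, truth) == 0
            assert np.abs(tree_distance_matrix(tree, ids) - D).max() < 1e-9

    def test_agrees_with_dendropy_nj(self):
        # independent implementation as cross-check, on a noisy matrix
        rng = np.random.default_rng(7)
        truth = simulate_tree(7, 3)
        ids = tuple(f"O{i+1}" for i in range(7))
        D = tree_distance_matrix(truth, ids)
        noise = rng.normal(0, 1e-3, D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        D = np.abs(D)
        mine = neighbor_joining(DissimilarityMatrix(ids, D))
        csv = "," + ",".join(ids) + "\n" + "\n".join(
            ids[i] + "," + ",".join(str(x) for x in D[i]) for i in range(7))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        theirs = pdm.nj_tree()
        assert robinson_foulds(mine, theirs) == 0

    def test_leaf_set_preserved(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 9))
            m = rng.random((n, n)) * 5
            m = m + m.T
            np.fill_diagonal(m, 0.0)
            ids = tuple(f"T{i}" for i in range(n))
            tree = neighbor_joining(DissimilarityMatrix(ids, m))
            leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
            assert leaves == sorted(ids)

    def test_too_few_taxa_refused(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DissimilarityMatrix(("A", "B"), np.zeros((2, 2))))

    def test_non_finite_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        with pytest.raises(ValidationError):
            neighbor_joining(DissimilarityMatrix(("A", "B", "C"), m))

    def test_deterministic_newick(self, rng):
        m = rng.random((5, 5))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        ids = tuple("ABCDE")
        t1 = as_newick(neighbor_joining(DissimilarityMatrix(ids, m)))
        t2 = as_newick(neighbor_joining(DissimilarityMatrix(ids, m.copy())))
        assert t1 == t2


class TestRobinsonFoulds:
    def test_identity(self):
        t = simulate_tree(6, 1)
        assert robinson_foulds(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,C:1):1,(B:1,D:1):1);", schema="newick")
        assert robinson_foulds(t1, t2) == 2

    def test_symmetric(self):
        for seed in range(10):
            t1 = simulate_tree(6, seed)
            t2 = simulate_tree(6, seed + 100)
            assert robinson_foulds(t1, t2) == robinson_foulds(t2, t1)

    def test_leaf_mismatch_rejected(self):
        t1 = simulate_tree(5, 0)
        t2 = simulate_tree(6, 0)
        with pytest.raises(ValidationError):
            robinson_foulds(t1, t2)
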