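import itertools

import numpy as np
import pytest

from metpathcomp.coevolution import (
    D1,
    D2,
    D3,
    D4,
    CoevParams,
    categorize_page,
    cluster_pathways,
    coevolution_matrix,
    CoevolutionMatrix,
    entry_distance,
    hamming_component,
    l1_component,
    pathway_distance,
)
from metpathcomp.pages import build_page_stack
from metpathcomp.pathway_io import (
    BOTH_MISSING,
    ONE_MISSING,
    Page,
    PageStack,
    ValidationError,
)

from conftest import random_page

CATS = (D1, D2, D3, D4)


class TestCategoryTable:
    @pytest.mark.parametrize("x", CATS)
    def test_identical_categories_cost_nothing(self, x):
        assert entry_distance(x, x) == 0.0

    def test_opposed_one_sided_patterns(self):
        assert entry_distance(D3, D4) == 2.0
        assert entry_distance(D4, D3) == 2.0

    @pytest.mark.parametrize("one_sided", (D3, D4))
    @pytest.mark.parametrize("shared", (D1, D2))
    def test_cross_patterns(self, one_sided, shared):
        assert entry_distance(one_sided, shared) == 1.0
        assert entry_distance(shared, one_sided) == 1.0

    def test_d1_d2_completion_default_and_override(self):
        assert entry_distance(D1, D2) == 2.0
        assert entry_distance(D2, D1) == 2.0
        params = CoevParams(d1_d2_distance=1.5)
        assert entry_distance(D1, D2, params) == 1.5

    def test_table_is_a_metric(self):
        # symmetry + triangle inequality over all category triples
        for x, y in itertools.product(CATS, CATS):
            assert entry_distance(x, y) == entry_distance(y, x)
        for x, y, z in itertools.product(CATS, CATS, CATS):
            assert (entry_distance(x, z)
                    <= entry_distance(x, y) + entry_distance(y, z))


class TestCategorize:
    def test_from_sentinel_pattern(self):
        page = Page.from_entries("p", ("O1", "O2"), [
            [0.0, ONE_MISSING], [ONE_MISSING, BOTH_MISSING]])
        cats = categorize_page(page)
        assert cats[0, 0] == D2 and cats[1, 1] == D1
        assert cats[0, 1] == D3 and cats[1, 0] == D4

    def test_presence_contradiction_rejected(self):
        page = Page.from_entries("p", ("O1", "O2"), [[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValidationError):
            categorize_page(page, presence=np.array([True, False]))


def page_from_presence(pathway, organisms, present, score=-1.0):
    n = len(organisms)
    entries = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if present[i] and present[j]:
                entries[i][j] = 0.0 if i == j else score
            elif not present[i] and not present[j]:
                entries[i][j] = BOTH_MISSING
            else:
                entries[i][j] = ONE_MISSING
    return Page.from_entries(pathway, organisms, entries)


class TestHamming:
    def test_identical_patterns_give_zero(self, rng):
        for _ in range(10):
            page = random_page(rng, n=4, absent=("O2",))
            c = categorize_page(page)
            assert hamming_component(c, c) == 0.0

    def test_one_pathway_partially_lost(self):
        # A present in both organisms, B only in the first
        orgs = ("O1", "O2")
        a = categorize_page(page_from_presence("A", orgs, [True, True]))
        b = categorize_page(page_from_presence("B", orgs, [True, False]))
        # entries: (0,0) D2/D2=0, (1,1) D2/D1=2, (0,1) D2/D3=1, (1,0) D2/D4=1
        assert hamming_component(a, b) == 1.0

    def test_complementary_presence(self):
        orgs = ("O1", "O2")
        a = categorize_page(page_from_presence("A", orgs, [True, False]))
        b = categorize_page(page_from_presence("B", orgs, [False, True]))
        # off-diagonals D3/D4 and D4/D3 = 2 each; diagonals D2/D1 = 2 each
        assert hamming_component(a, b) == 2.0

    def test_triangle_normalization(self):
        orgs = ("O1", "O2")
        a = categorize_page(page_from_presence("A", orgs, [True, False]))
        b = categorize_page(page_from_presence("B", orgs, [False, True]))
        params = CoevParams(triangle=True)
        assert hamming_component(a, b, params) == 2.0  # single (0,1) entry

    def test_range_and_zero_iff_same_presence(self, rng):
        orgs = tuple(f"O{i}" for i in range(5))
        for _ in range(30):
            pa = list(rng.random(5) < 0.6)
            pb = list(rng.random(5) < 0.6)
            a = categorize_page(page_from_presence("A", orgs, pa))
            b = categorize_page(page_from_presence("B", orgs, pb))
            h = hamming_component(a, b)
            assert 0.0 <= h <= 2.0
            assert (h == 0.0) == (pa == pb)


class TestL1:
    def test_identical_pages(self, rng):
        page = random_page(rng, n=4)
        assert l1_component(page, page) == 0.0

    def test_mean_absolute_difference(self):
        orgs = ("O1", "O2")
        p1 = Page.from_entries("A", orgs, [[0.0, -1.0], [-1.0, 0.0]])
        p2 = Page.from_entries("B", orgs, [[0.0, -2.0], [-2.0, 0.0]])
        # qualifying entries: both off-diagonals and both zero diagonals
        assert l1_component(p1, p2) == pytest.approx((1 + 1 + 0 + 0) / 4)

    def test_disjoint_presence_falls_back_to_zero(self, caplog):
        orgs = ("O1", "O2")
        p1 = page_from_presence("A", orgs, [True, False])
        p2 = page_from_presence("B", orgs, [False, True])
        with caplog.at_level("WARNING"):
            assert l1_component(p1, p2) == 0.0
        assert any("no organism pair" in r.message for r in caplog.records)


class TestCombinedDistance:
    def test_zero_components(self, rng):
        page = random_page(rng, n=3)
        assert pathway_distance(page, page) == 0.0

    def test_weighted_average_form(self):
        orgs = ("O1", "O2")
        a = page_from_presence("A", orgs, [True, True])
        b = page_from_presence("B", orgs, [True, False])
        # H = 1, L = 0 (no shared numeric off-diagonal beyond diagonal zeros)
        assert pathway_distance(a, b) == pytest.approx(100.0 / 101.0)

    def test_weighted_sum_variant(self):
        orgs = ("O1", "O2")
        a = page_from_presence("A", orgs, [True, True])
        b = page_from_presence("B", orgs, [True, False])
        params = CoevParams(combine="weighted_sum")
        assert pathway_distance(a, b, params) == pytest.approx(100.0)

    def test_between_components(self, rng):
        for _ in range(20):
            p1 = random_page(rng, n=4, pathway="A",
                             absent=("O3",) if rng.random() < 0.5 else ())
            p2 = random_page(rng, n=4, pathway="B",
                             absent=("O1",) if rng.random() < 0.5 else ())
            h = hamming_component(categorize_page(p1), categorize_page(p2))
            l1 = l1_component(p1, p2)
            d = pathway_distance(p1, p2)
            assert min(h, l1) - 1e-12 <= d <= max(h, l1) + 1e-12


class TestCoevolutionMatrix:
    def test_identical_pages_give_zero_matrix(self, rng):
        page = random_page(rng, n=4)
        pages = tuple(
            Page(f"p{k}", page.organisms, page.scores, page.status)
            for k in range(3))
        stack = PageStack(page.organisms, tuple(f"p{k}" for k in range(3)),
                          pages)
        cm = coevolution_matrix(stack)
        assert np.array_equal(cm.distances, np.zeros((3, 3)))

    def test_matches_scalar_operations(self, toy_table):
        stack, _ = build_page_stack(toy_table)
        cm = coevolution_matrix(stack)
        p1, p2 = stack.pages
        assert cm.distances[0, 1] == pytest.approx(pathway_distance(p1, p2))
        assert cm.hamming[0, 1] == pytest.approx(hamming_component(
            categorize_page(p1), categorize_page(p2)))
        assert cm.l1[0, 1] == pytest.approx(l1_component(p1, p2))

    def test_symmetry_and_zero_diagonal(self, rng):
        orgs = tuple(f"O{i+1}" for i in range(4))
        pages, names = [], []
        for k in range(5):
            absent = tuple(o for o in orgs if rng.random() < 0.3)
            absent = absent if len(absent) < 4 else absent[:3]
            pages.append(random_page(rng, n=4, pathway=f"p{k}", absent=absent))
            names.append(f"p{k}")
        stack = PageStack(orgs, tuple(names), tuple(pages))
        cm = coevolution_matrix(stack)
        assert np.array_equal(cm.distances, cm.distances.T)
        assert np.all(np.diagonal(cm.distances) == 0.0)


class TestClustering:
    def planted(self, rng, m=12, sep=1.0, jitter=0.01):
        half = m // 2
        labels = np.array([0] * half + [1] * (m - half))
        d = np.where(labels[:, None] != labels[None, :], sep, jitter)
        d = d + rng.normal(0, jitter / 10, (m, m))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d = np.abs(d)
        cm = CoevolutionMatrix(tuple(f"p{i}" for i in range(m)), d,
                               np.zeros((m, m)), np.zeros((m, m)))
        return cm, labels

    def test_recovers_planted_blocks(self, rng):
        cm, truth = self.planted(rng)
        labels, k = cluster_pathways(cm)
        assert k == 2
        from sklearn.metrics import rand_score
        assert rand_score(truth, labels) == 1.0

    def test_forced_k_partitions_everything(self, rng):
        cm, _ = self.planted(rng)
        labels, k = cluster_pathways(cm, k=3)
        assert k == 3
        assert len(labels) == 12 and set(labels) == {0, 1, 2}

    def test_permutation_equivariance(self, rng):
        cm, _ = self.planted(rng, m=10)
        labels, _ = cluster_pathways(cm)
        perm = rng.permutation(10)
        cm2 = CoevolutionMatrix(tuple(cm.pathways[i] for i in perm),
                                cm.distances[np.ix_(perm, perm)],
                                cm.hamming[np.ix_(perm, perm)],
                                cm.l1[np.ix_(perm, perm)])
        labels2, _ = cluster_pathways(cm2)
        from sklearn.metrics import rand_score
        assert rand_score(labels[perm], labels2) == 1.0

    def test_single_pathway_refused(self):
        cm = CoevolutionMatrix(("p0",), np.zeros((1, 1)),
                               np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ValidationError):
            cluster_pathways(cm)
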