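"""From weighted pages to a phylogeny.

The weighted pages are summed along the pathway axis into a single
organism-by-organism similarity matrix (after thresholding and
reweighting, every entry is 0 or a page weight, so plain addition is
well defined). Similarity becomes dissimilarity by subtracting every
element from the global maximum — which sits on the diagonal whenever
every organism attains perfect self-similarity — and forcing the diagonal
to zero. The tree is then built by the classical Saitou-Nei
neighbor-joining algorithm, implemented here with a pinned deterministic
tie-break (among equal Q-criterion values, the lexicographically smallest
index pair is joined) so that identical inputs always yield byte-identical
Newick output. Negative branch lengths, which NJ can produce on
non-additive input, are clamped to zero.

Trees are :class:`dendropy.Tree` objects throughout; Robinson-Foulds
distances are symmetric-difference counts of non-trivial bipartitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .pathway_io import ValidationError
from .weighting import WeightedPage

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "collapse_stack",
    "to_dissimilarity",
    "neighbor_joining",
    "robinson_foulds",
    "tree_distance_matrix",
    "write_newick",
    "read_newick",
]


@dataclass
class SimilarityMatrix:
    organisms: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.organisms)
        if self.matrix.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("similarity matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValidationError("similarity entries must be >= 0")


@dataclass
class DissimilarityMatrix:
    organisms: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.organisms)
        if self.matrix.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(self.matrix < 0):
            raise ValidationError("dissimilarity entries must be >= 0")
        if np.any(np.diagonal(self.matrix) != 0):
            raise ValidationError("dissimilarity diagonal must be 0")


def collapse_stack(weighted: Sequence[WeightedPage]) -> SimilarityMatrix:
    """Sum the weighted pages element-wise into one similarity matrix."""
    if not weighted:
        raise ValidationError("no weighted pages to collapse")
    orgs = weighted[0].organisms
    for wp in weighted:
        if wp.organisms != orgs:
            raise ValidationError(
                f"page {wp.pathway_id!r} has a different organism ordering"
            )
    total = np.sum([wp.matrix for wp in weighted], axis=0)
    return SimilarityMatrix(orgs, total)


def to_dissimilarity(sim: SimilarityMatrix) -> DissimilarityMatrix:
    """Subtract every element from the global maximum; zero the diagonal.

    With b = false the diagonal similarities can differ between organisms,
    in which case the maximum need not equal the first diagonal entry and
    the subtracted diagonal need not vanish; both situations are logged
    and the diagonal is forced to zero (a tree method needs zero
    self-distance).
    """
    m = sim.matrix
    mx = float(m.max()) if m.size else 0.0
    if m[0, 0] != mx:
        logger.warning(
            "maximum similarity %g is not the first diagonal entry (%g); "
            "using the global maximum", mx, m[0, 0],
        )
    d = mx - m
    resid = np.diagonal(d)
    nonzero = np.nonzero(resid)[0]
    if nonzero.size:
        logger.warning(
            "nonzero self-dissimilarity forced to 0 for organisms: %s",
            ", ".join(sim.organisms[i] for i in nonzero),
        )
        d = d.copy()
        np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(sim.organisms, d)


def neighbor_joining(dis: DissimilarityMatrix) -> dendropy.Tree:
    """Classical neighbor joining with deterministic tie-breaking.

    Iteratively joins the pair minimizing
    Q(i, j) = (N - 2) d(i, j) - r_i - r_j (r = row sums over active
    nodes), with branch lengths by the standard formulas; equal Q values
    are resolved toward the smallest (i, j) index pair. Exact on additive
    matrices. Requires n >= 3 taxa and finite entries.
    """
    ids = dis.organisms
    n = len(ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 organisms")
    if not np.all(np.isfinite(dis.matrix)):
        raise ValidationError("dissimilarity matrix has non-finite entries")

    taxa = dendropy.TaxonNamespace(list(ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for name in ids:
        leaf = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes.append(leaf)

    D = dis.matrix.astype(float).copy()
    active = list(range(n))  # indices into D rows/cols and `nodes`

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        N = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(N):
            for aj in range(ai + 1, N):
                i, j = active[ai], active[aj]
                q = (N - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        # reuse row i for the new node, retire row j
        newdist = {k: 0.5 * (D[i, k] + D[j, k] - D[i, j])
                   for k in active if k not in (i, j)}
        for k, v in newdist.items():
            D[i, k] = D[k, i] = v
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = clamp(lk)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    from pathlib import Path
    Path(path).write_text(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _common_namespace(t1: dendropy.Tree, t2: dendropy.Tree
                      ) -> tuple[dendropy.Tree, dendropy.Tree]:
    ns = dendropy.TaxonNamespace()
    c1 = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns)
    c2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns)
    c1.is_rooted = False
    c2.is_rooted = False
    return c1, c2


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance between two unrooted trees.

    Counts the bipartitions present in exactly one of the trees; both must
    cover the same leaf set.
    """
    l1 = sorted(leaf.taxon.label for leaf in t1.leaf_node_iter())
    l2 = sorted(leaf.taxon.label for leaf in t2.leaf_node_iter())
    if l1 != l2:
        raise ValidationError("trees have different leaf sets")
    c1, c2 = _common_namespace(t1, t2)
    return int(treecompare.symmetric_difference(c1, c2))


def tree_distance_matrix(tree: dendropy.Tree, ids: Sequence[str]
                         ) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a tree, in the given id order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out
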