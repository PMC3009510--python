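"""Detecting co-evolving pathways by comparing their pages.

Two pathways that gained, lost and modified enzymes along the same
lineages leave similar traces in their pages. The page-to-page distance
has two parts:

* A generalized Hamming component H. Every page entry is put into one of
  four appearance categories — d1: the pathway is absent from both
  organisms; d2: present in both; d3: present in the first organism only;
  d4: present in the second only. For an entry where one pathway shows
  category x and the other category y, a lookup table D(x, y) charges 0
  when x == y, 2 for the fully opposed one-sided patterns (d3 vs d4), and
  1 for every pairing of a one-sided pattern with d1 or d2. The d1-vs-d2
  pairing, which also disagrees in both organisms, defaults to 2 by
  analogy (configurable). H is the mean of D over all n^2 ordered entries
  (optionally over the strict upper triangle).
* An L1 component L: the mean absolute difference of raw alignment scores
  over the entries where both pathways are present in both organisms
  (0, with a warning, when no such entry exists).

The two are combined as a weighted average (W_p * H + L) / (W_p + 1) with
W_p = 100 by default — the coarse presence/absence signal dominates, the
score signal refines. Raw score pages (pre-thresholding) are the intended
input; quantized weighted pages would make L meaningless.

Pathways are clustered on the resulting m x m distance matrix by
average-linkage agglomerative clustering, with the cluster count chosen
by maximal silhouette when not given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .pathway_io import (
    STATUS_BOTH_MISSING,
    STATUS_NUMERIC,
    STATUS_ONE_MISSING,
    Page,
    PageStack,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "D1", "D2", "D3", "D4",
    "CoevParams",
    "CoevolutionMatrix",
    "entry_distance",
    "categorize_page",
    "hamming_component",
    "l1_component",
    "pathway_distance",
    "coevolution_matrix",
    "cluster_pathways",
]

# appearance categories of a page entry (i, j), i the "first" organism
D1 = 1  # absent in both
D2 = 2  # present in both
D3 = 3  # present in i, absent in j
D4 = 4  # absent in i, present in j


@dataclass(frozen=True)
class CoevParams:
    """Parameters of the page-to-page distance.

    w_p : weight of the Hamming component in the combination (default 100).
    d1_d2_distance : completion of the category table for the unlisted
        d1-vs-d2 pairing (default 2: the patterns disagree in both
        organisms, like d3 vs d4).
    triangle : normalize H over the strict upper triangle instead of all
        n^2 ordered entries.
    combine : "weighted_average" (default) or "weighted_sum".
    """

    w_p: float = 100.0
    d1_d2_distance: float = 2.0
    triangle: bool = False
    combine: str = "weighted_average"

    def __post_init__(self) -> None:
        if self.w_p <= 0:
            raise ValidationError("w_p must be > 0")
        if self.combine not in ("weighted_average", "weighted_sum"):
            raise ValidationError(
                "combine must be 'weighted_average' or 'weighted_sum'"
            )

    def d_table(self) -> np.ndarray:
        """The 4x4 category-distance table, indexed by (x - 1, y - 1)."""
        t = np.array([
            # d1  d2  d3  d4
            [0.0, self.d1_d2_distance, 1.0, 1.0],   # d1
            [self.d1_d2_distance, 0.0, 1.0, 1.0],   # d2
            [1.0, 1.0, 0.0, 2.0],                   # d3
            [1.0, 1.0, 2.0, 0.0],                   # d4
        ])
        return t


def entry_distance(x: int, y: int, params: CoevParams = CoevParams()) -> float:
    """Per-entry contribution D(x, y) for categories x, y in {D1..D4}."""
    return float(params.d_table()[x - 1, y - 1])


def categorize_page(page: Page, presence: Optional[np.ndarray] = None
                    ) -> np.ndarray:
    """The n x n category matrix of a page.

    ``presence`` is the pathway's boolean presence column in page organism
    order; when omitted it is recovered from the page diagonal (numeric
    self-score means present). The page's sentinel pattern is checked for
    consistency with the presence pattern.
    """
    diag_present = np.diagonal(page.status) == STATUS_NUMERIC
    if presence is None:
        presence = diag_present
    else:
        presence = np.asarray(presence, dtype=bool)
        if presence.shape != (page.n,):
            raise ValidationError("presence vector length mismatch")
        if not np.array_equal(presence, diag_present):
            raise ValidationError(
                f"page {page.pathway_id!r} diagonal contradicts the "
                "presence pattern"
            )
    pi = presence[:, None]
    pj = presence[None, :]
    cats = np.where(pi & pj, D2,
                    np.where(~pi & ~pj, D1, np.where(pi, D3, D4)))
    expected = np.where(pi & pj, STATUS_NUMERIC,
                        np.where(~pi & ~pj, STATUS_BOTH_MISSING,
                                 STATUS_ONE_MISSING))
    if not np.array_equal(page.status, expected):
        raise ValidationError(
            f"page {page.pathway_id!r} sentinels contradict the presence "
            "pattern"
        )
    return cats.astype(np.int8)


def hamming_component(c1: np.ndarray, c2: np.ndarray,
                      params: CoevParams = CoevParams()) -> float:
    """Mean category distance between two category matrices."""
    if c1.shape != c2.shape:
        raise ValidationError("category matrices have different shapes")
    table = params.d_table()
    per_entry = table[c1 - 1, c2 - 1]
    if params.triangle:
        iu = np.triu_indices(c1.shape[0], k=1)
        vals = per_entry[iu]
        return float(vals.mean()) if vals.size else 0.0
    return float(per_entry.mean())


def l1_component(p1: Page, p2: Page) -> float:
    """Mean |score difference| over entries numeric in both pages."""
    if p1.organisms != p2.organisms:
        raise ValidationError("pages have different organism orderings")
    both = p1.numeric_mask() & p2.numeric_mask()
    if not both.any():
        logger.warning(
            "pathways %r and %r share no organism pair where both are "
            "present; L1 component set to 0", p1.pathway_id, p2.pathway_id,
        )
        return 0.0
    return float(np.abs(p1.scores[both] - p2.scores[both]).mean())


def _combine(h: float, l1: float, params: CoevParams) -> float:
    if params.combine == "weighted_sum":
        return params.w_p * h + l1
    return (params.w_p * h + l1) / (params.w_p + 1.0)


def pathway_distance(p1: Page, p2: Page,
                     params: CoevParams = CoevParams()) -> float:
    """Combined evolutionary distance between two pathways' pages."""
    h = hamming_component(categorize_page(p1), categorize_page(p2), params)
    l1 = l1_component(p1, p2)
    return _combine(h, l1, params)


@dataclass
class CoevolutionMatrix:
    """m x m pathway distances plus the retained H and L components."""

    pathways: tuple[str, ...]
    distances: np.ndarray
    hamming: np.ndarray
    l1: np.ndarray

    def __post_init__(self) -> None:
        self.pathways = tuple(self.pathways)
        m = len(self.pathways)
        for a in (self.distances, self.hamming, self.l1):
            if a.shape != (m, m):
                raise ValidationError("coevolution matrix shape mismatch")
        if not np.allclose(self.distances, self.distances.T):
            raise ValidationError("coevolution matrix must be symmetric")
        if np.any(np.diagonal(self.distances) != 0):
            raise ValidationError("coevolution matrix diagonal must be 0")


def coevolution_matrix(stack: PageStack,
                       params: CoevParams = CoevParams()) -> CoevolutionMatrix:
    """All-pairs page comparison over a stack of raw score pages."""
    m = stack.m
    cats = [categorize_page(p) for p in stack.pages]
    dist = np.zeros((m, m))
    ham = np.zeros((m, m))
    l1m = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            h = hamming_component(cats[a], cats[b], params)
            l1 = l1_component(stack.pages[a], stack.pages[b])
            ham[a, b] = ham[b, a] = h
            l1m[a, b] = l1m[b, a] = l1
            dist[a, b] = dist[b, a] = _combine(h, l1, params)
    return CoevolutionMatrix(stack.pathways, dist, ham, l1m)


def cluster_pathways(cm: CoevolutionMatrix, k: Optional[int] = None
                     ) -> tuple[np.ndarray, int]:
    """Average-linkage clustering of pathways on the coevolution matrix.

    With ``k`` unset, the cluster count is chosen in 2..min(10, m - 1) by
    maximal silhouette (ties toward fewer clusters). Returns the label
    array (aligned with ``cm.pathways``) and the chosen k.
    """
    m = len(cm.pathways)
    if m < 2:
        raise ValidationError("clustering needs at least 2 pathways")

    def fit(kk: int) -> np.ndarray:
        model = AgglomerativeClustering(
            n_clusters=kk, metric="precomputed", linkage="average"
        )
        return model.fit_predict(cm.distances)

    if k is not None:
        if not 1 <= k <= m:
            raise ValidationError(f"k={k} out of range 1..{m}")
        if k == 1:
            return np.zeros(m, dtype=int), 1
        return fit(k), k

    candidates = range(2, min(10, m - 1) + 1)
    best_k, best_labels, best_score = None, None, -np.inf
    for kk in candidates:
        labels = fit(kk)
        try:
            score = silhouette_score(cm.distances, labels, metric="precomputed")
        except ValueError:
            continue
        if np.isnan(score):
            continue
        if score > best_score:
            best_k, best_labels, best_score = kk, labels, score
    if best_k is None:  # e.g. m == 2, or a degenerate all-zero matrix
        best_k = 2
        best_labels = fit(2)
    return best_labels, best_k
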