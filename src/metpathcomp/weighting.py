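"""Threshold graphs and information-content weighting of pages.

Raw alignment scores are hard to combine across pathways of very different
size and coverage, so each page is binarized: organisms i and j are joined
by an edge of the pathway's *threshold graph* (TG) when their similarity
score clears a threshold t (scores are <= 0; every score at or above t
counts equally). A pathway absent from exactly one of the two organisms
never produces an edge; a pathway absent from both produces an edge exactly
when the Boolean confidence parameter b is true (joint absence read as
similarity in the lacking).

Each TG then receives a single weight

    w = sum_v h(deg(v) / |V|),   h(p) = -p log2 p - (1 - p) log2 (1 - p),

the sum of the binary entropies of the normalized node degrees (self-loops
included — a present pathway always clears the threshold against itself, so
a fully connected TG reaches degree |V| on every node). w is 0 for the two
uninformative extremes — every degree 0 (no organism resembles any other)
and every degree |V| (all organisms alike) — and is largest when degrees
sit near |V|/2, where the pathway best splits the organisms into groups.
The weight function is pluggable should a different entropy-style summary
be preferred.

Reweighting replaces each page by the adjacency matrix of its weighted TG:
w on edges, 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .pathway_io import (
    STATUS_BOTH_MISSING,
    STATUS_NUMERIC,
    Page,
    PageStack,
    ValidationError,
)

__all__ = [
    "ThresholdGraph",
    "WeightedPage",
    "binary_entropy",
    "build_threshold_graph",
    "graph_weight",
    "reweight_page",
    "weight_page_stack",
    "rank_pathways_by_weight",
]


@dataclass
class ThresholdGraph:
    """The n-organism graph of a page at threshold ``t`` (weight optional)."""

    pathway_id: str
    organisms: tuple[str, ...]
    adjacency: np.ndarray  # boolean n x n, symmetric, self-loops allowed
    t: float
    b: bool
    weight: float | None = None

    @property
    def n(self) -> int:
        return len(self.organisms)

    def degrees(self) -> np.ndarray:
        """Out-degree per node, self-loop counted once (in == out here)."""
        return self.adjacency.sum(axis=1)


@dataclass
class WeightedPage:
    """Adjacency matrix of a weighted TG: entries are 0 or the TG weight."""

    pathway_id: str
    organisms: tuple[str, ...]
    matrix: np.ndarray
    weight: float


def build_threshold_graph(page: Page, t: float, b: bool,
                          strict: bool = False) -> ThresholdGraph:
    """Edges where the score clears ``t`` (``>= t``, or ``> t`` when
    ``strict``), plus all both-missing pairs when ``b`` is true.

    One-missing entries never yield an edge.
    """
    numeric = page.status == STATUS_NUMERIC
    with np.errstate(invalid="ignore"):
        over = page.scores > t if strict else page.scores >= t
    adj = numeric & over
    if b:
        adj = adj | (page.status == STATUS_BOTH_MISSING)
    return ThresholdGraph(page.pathway_id, page.organisms, adj, t, b)


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """h(p) in bits, with h(0) = h(1) = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out if out.ndim else float(out)


def graph_weight(tg: ThresholdGraph,
                 node_term: Callable[[np.ndarray], np.ndarray] = binary_entropy
                 ) -> float:
    """Information weight of a TG: sum over nodes of ``node_term(deg/|V|)``.

    With the default binary-entropy term, w = 0 when all degrees are 0 and
    when all degrees are |V|, and 0 <= w <= |V| always.
    """
    p = tg.degrees() / tg.n
    w = float(np.sum(node_term(p)))
    tg.weight = w
    return w


def reweight_page(page: Page, tg: ThresholdGraph) -> WeightedPage:
    """Replace the page by its weighted TG adjacency: w on edges, else 0."""
    if tg.organisms != page.organisms:
        raise ValidationError("threshold graph does not match the page")
    w = tg.weight if tg.weight is not None else graph_weight(tg)
    matrix = np.where(tg.adjacency, w, 0.0)
    return WeightedPage(page.pathway_id, page.organisms, matrix, w)


def weight_page_stack(stack: PageStack, t: float, b: bool,
                      strict: bool = False,
                      node_term: Callable[[np.ndarray], np.ndarray] = binary_entropy,
                      ) -> tuple[list[WeightedPage], list[ThresholdGraph]]:
    """Threshold, weigh and reweight every page of a stack."""
    weighted, tgs = [], []
    for page in stack.pages:
        tg = build_threshold_graph(page, t, b, strict=strict)
        graph_weight(tg, node_term)
        weighted.append(reweight_page(page, tg))
        tgs.append(tg)
    return weighted, tgs


def rank_pathways_by_weight(tgs: Sequence[ThresholdGraph]) -> pd.DataFrame:
    """Pathways sorted by TG weight, descending; ties by pathway id.

    High-weight pathways are the ones whose presence/similarity pattern
    best partitions the organisms, and hence the first candidates when
    tracing which pathways drive the phylogeny.
    """
    rows = [(tg.pathway_id, tg.weight if tg.weight is not None else graph_weight(tg))
            for tg in tgs]
    df = pd.DataFrame(rows, columns=["pathway_id", "weight"])
    df = df.sort_values(["weight", "pathway_id"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)
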