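"""Assemble per-pathway all-against-all similarity pages.

For every pathway the table knows about, each unordered organism pair is
aligned once (the smaller instance as query, equal sizes resolved by taking
the second organism's instance as query) and the score written symmetrically
into an n x n page. Where the pathway is missing the page carries sentinels:
ONE_MISSING when exactly one organism lacks it, BOTH_MISSING when both do.
Diagonal entries are 0 where the pathway is present (a perfect
self-alignment, short-circuited without invoking the aligner) and
BOTH_MISSING where it is absent.

Stacking the m pages gives the 3D array the rest of the pipeline consumes;
the work grows as O(m * n^2) alignment calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AlignParams, align_pathways
from .pathway_io import (
    ABSENT,
    STATUS_BOTH_MISSING,
    STATUS_NUMERIC,
    STATUS_ONE_MISSING,
    InstanceTable,
    Page,
    PageStack,
    read_page,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_page",
    "build_page_stack",
    "AlignmentCountReport",
    "full_run_alignment_count",
    "read_page_stack",
]


@dataclass(frozen=True)
class AlignmentCountReport:
    """How many alignments a stack build performed (or would perform)."""

    pairwise_alignments: int      # unordered present-present pairs, aligned once
    self_alignments: int          # diagonal entries, short-circuited to 0
    per_pathway: dict[str, int]   # pairwise count per pathway

    @property
    def total(self) -> int:
        return self.pairwise_alignments + self.self_alignments

    def to_json(self) -> dict:
        return {
            "pairwise_alignments": self.pairwise_alignments,
            "self_alignments": self.self_alignments,
            "total": self.total,
            "per_pathway": dict(self.per_pathway),
        }


def full_run_alignment_count(n_organisms: int, n_pathways: int) -> int:
    """Alignments in a full all-against-all run: every ordered pair of
    distinct organisms for every pathway, i.e. ``m * n * (n - 1)``.

    This is the raw workload of running the external alignment engine on
    every cell of the 3D array; the in-package builder halves it by
    aligning each unordered pair once and mirroring.
    """
    return n_pathways * n_organisms * (n_organisms - 1)


def build_page(table: InstanceTable, pathway: str,
               params: AlignParams = AlignParams()) -> Page:
    """Build the similarity page of one pathway across all organisms."""
    orgs = table.organisms
    n = len(orgs)
    scores = np.full((n, n), np.nan)
    status = np.zeros((n, n), dtype=np.int8)
    insts = [table.cell(o, pathway) for o in orgs]
    for i in range(n):
        if insts[i] is ABSENT:
            status[i, i] = STATUS_BOTH_MISSING
        else:
            scores[i, i] = 0.0  # perfect self-similarity, no aligner call
        for j in range(i + 1, n):
            a, b = insts[i], insts[j]
            if a is ABSENT and b is ABSENT:
                status[i, j] = status[j, i] = STATUS_BOTH_MISSING
            elif a is ABSENT or b is ABSENT:
                status[i, j] = status[j, i] = STATUS_ONE_MISSING
            else:
                if a.n_nodes < b.n_nodes:
                    res = align_pathways(a, b, params)
                else:
                    # equal sizes fall here: second instance becomes query
                    res = align_pathways(b, a, params)
                scores[i, j] = scores[j, i] = res.score
                status[i, j] = status[j, i] = STATUS_NUMERIC
    return Page(pathway, orgs, scores, status)


def build_page_stack(table: InstanceTable,
                     params: AlignParams = AlignParams()
                     ) -> tuple[PageStack, AlignmentCountReport]:
    """Build one page per pathway and report the alignment counts."""
    pages = []
    per_pathway: dict[str, int] = {}
    selfs = 0
    for pw in table.pathways:
        present = int(table.presence_column(pw).sum())
        per_pathway[pw] = present * (present - 1) // 2
        selfs += present
        pages.append(build_page(table, pw, params))
    report = AlignmentCountReport(
        pairwise_alignments=sum(per_pathway.values()),
        self_alignments=selfs,
        per_pathway=per_pathway,
    )
    logger.info(
        "built %d pages over %d organisms (%d pairwise alignments)",
        table.n_pathways, table.n_organisms, report.pairwise_alignments,
    )
    stack = PageStack(table.organisms, table.pathways, tuple(pages))
    return stack, report


def read_page_stack(page_dir: str | Path, pathways: list[str] | None = None
                    ) -> PageStack:
    """Ingest precomputed pages (one TSV per pathway) from a directory.

    This is the entry point for users with output from a real alignment
    engine; ``pathways`` fixes the stacking order (default: sorted file
    names).
    """
    page_dir = Path(page_dir)
    files = {p.stem: p for p in sorted(page_dir.glob("*.tsv"))}
    if pathways is None:
        pathways = sorted(files)
    pages = [read_page(files[pw]) for pw in pathways]
    if not pages:
        raise FileNotFoundError(f"no page TSV files under {page_dir}")
    return PageStack(pages[0].organisms, tuple(pathways), tuple(pages))
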