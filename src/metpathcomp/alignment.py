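"""Pairwise alignment of pathway instances.

Scores how similar two occurrences of the same pathway are, combining
enzyme identity (EC-number agreement) with topology (conservation of the
reaction order). The score of an injective partial mapping M from query
nodes to target nodes is

    sum_{u in dom(M)} ec_similarity(u, M(u))        (node term, <= 0)
  + d * |query nodes outside dom(M)|                (deletion term, d <= 0)
  + sum over query edges (u, v) with both ends mapped:
        0 if a directed path M(u) -> M(v) exists in the target, else delta

and the alignment score is the maximum over all such mappings. All three
terms are non-positive, so scores are always <= 0 and an instance aligned
with itself scores exactly 0; higher means more similar.

Path conservation uses reachability by default (an edge of the query may be
realized by any directed path of the target, tolerating inserted enzymes);
``path_conservation="edge"`` restricts it to direct edges.

The optimum is found exactly by branch-and-bound for queries of up to
``exact_search_cap`` nodes; larger queries fall back to a deterministic
greedy assignment (best EC similarity, lexicographic tie-breaks) scored
under the same objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from .pathway_io import PathwayInstance, ValidationError, validate_ec

__all__ = [
    "AlignParams",
    "AlignmentResult",
    "ec_similarity",
    "align_pathways",
    "brute_force_align",
]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for pathway alignment.

    deletion_score : penalty per unmatched query node (the engine's ``d``).
    ec_mismatch_penalty : cost per disagreeing EC field (``mu``).
    topology_gap_penalty : cost per non-conserved query edge (``delta``);
        defaults to the deletion score.
    exact_search_cap : largest query (node count) solved exactly.
    path_conservation : "reachability" (default) or "edge".
    """

    deletion_score: float = -2.0
    ec_mismatch_penalty: float = 1.0
    topology_gap_penalty: Optional[float] = None
    exact_search_cap: int = 12
    path_conservation: str = "reachability"

    def __post_init__(self) -> None:
        if self.deletion_score > 0:
            raise ValidationError("deletion_score must be <= 0")
        if self.ec_mismatch_penalty <= 0:
            raise ValidationError("ec_mismatch_penalty must be > 0")
        if self.topology_gap_penalty is not None and self.topology_gap_penalty > 0:
            raise ValidationError("topology_gap_penalty must be <= 0")
        if self.exact_search_cap < 1:
            raise ValidationError("exact_search_cap must be >= 1")
        if self.path_conservation not in ("reachability", "edge"):
            raise ValidationError(
                "path_conservation must be 'reachability' or 'edge'"
            )

    @property
    def delta(self) -> float:
        d = self.topology_gap_penalty
        return self.deletion_score if d is None else d


@dataclass(frozen=True)
class AlignmentResult:
    """An alignment: its score (<= 0), the node mapping, and the deletions."""

    score: float
    mapping: dict[str, str]
    unmatched_query_nodes: tuple[str, ...]


def ec_similarity(ec1: str, ec2: str, mu: float = 1.0) -> float:
    """Similarity of two EC labels: ``-mu * (4 - k)`` for a common prefix
    of ``k`` fields.

    A ``"-"`` wildcard field matches nothing and ends the prefix, so only
    fully concrete, identical labels score 0.
    """
    f1 = validate_ec(ec1)
    f2 = validate_ec(ec2)
    k = 0
    for a, b in zip(f1, f2):
        if a == "-" or b == "-" or a != b:
            break
        k += 1
    return -mu * (4 - k)


def _reachable(target: PathwayInstance, mode: str) -> dict[str, set[str]]:
    """For each target node, the set of nodes a directed path leads to."""
    succ: dict[str, set[str]] = {nid: set() for nid, _ in target.nodes}
    for u, v in target.edges:
        succ[u].add(v)
    if mode == "edge":
        return succ
    # transitive closure by repeated expansion (instances are small)
    reach = {u: set(vs) for u, vs in succ.items()}
    changed = True
    while changed:
        changed = False
        for u in reach:
            add = set().union(*(reach[v] for v in reach[u])) - reach[u] if reach[u] else set()
            if add:
                reach[u] |= add
                changed = True
    return reach


def score_mapping(query: PathwayInstance, target: PathwayInstance,
                  mapping: dict[str, str], params: AlignParams,
                  reach: dict[str, set[str]] | None = None) -> float:
    """Evaluate the alignment objective for one explicit mapping."""
    if reach is None:
        reach = _reachable(target, params.path_conservation)
    mu = params.ec_mismatch_penalty
    tgt_ec = dict(target.nodes)
    score = 0.0
    for u, ec in query.nodes:
        if u in mapping:
            score += ec_similarity(ec, tgt_ec[mapping[u]], mu)
        else:
            score += params.deletion_score
    for u, v in query.edges:
        if u in mapping and v in mapping:
            if mapping[v] not in reach[mapping[u]]:
                score += params.delta
    return score


def _result(query: PathwayInstance, mapping: dict[str, str],
            score: float) -> AlignmentResult:
    unmatched = tuple(nid for nid, _ in query.nodes if nid not in mapping)
    return AlignmentResult(score, dict(mapping), unmatched)


def _self_identical(a: PathwayInstance, b: PathwayInstance) -> bool:
    return a.nodes == b.nodes and set(a.edges) == set(b.edges)


def _exact_align(query: PathwayInstance, target: PathwayInstance,
                 params: AlignParams) -> AlignmentResult:
    """Branch-and-bound over partial injective maps.

    Query nodes are processed in lexicographic node-id order; for each, the
    candidate targets are tried in lexicographic order, then deletion. All
    score increments are <= 0, so a branch whose partial score cannot beat
    the incumbent is pruned; the first optimum in this deterministic order
    is returned.
    """
    reach = _reachable(target, params.path_conservation)
    mu = params.ec_mismatch_penalty
    d, delta = params.deletion_score, params.delta
    qnodes = sorted(query.nodes)  # (node_id, ec), lexicographic
    tnodes = sorted(target.nodes)
    # query edges incident to each node, against already-placed nodes
    in_edges: dict[str, list[str]] = {nid: [] for nid, _ in query.nodes}
    out_edges: dict[str, list[str]] = {nid: [] for nid, _ in query.nodes}
    for u, v in query.edges:
        out_edges[u].append(v)
        in_edges[v].append(u)

    best_score = -float("inf")
    best_map: dict[str, str] = {}
    mapping: dict[str, str] = {}
    used: set[str] = set()

    # admissible bound: the best any remaining query node could contribute,
    # ignoring target exclusivity and edge penalties (both only lower it)
    per_node_cap = [
        max(d, max(ec_similarity(ec, tec, mu) for _, tec in tnodes))
        for _, ec in qnodes
    ]
    suffix_cap = [0.0] * (len(qnodes) + 1)
    for i in range(len(qnodes) - 1, -1, -1):
        suffix_cap[i] = suffix_cap[i + 1] + per_node_cap[i]

    def edge_increment(u: str, t: str) -> float:
        inc = 0.0
        for v in out_edges[u]:
            if v in mapping and mapping[v] not in reach[t]:
                inc += delta
        for w in in_edges[u]:
            if w in mapping and t not in reach[mapping[w]]:
                inc += delta
        return inc

    def dfs(idx: int, partial: float) -> None:
        nonlocal best_score, best_map
        if partial + suffix_cap[idx] <= best_score:
            return
        if idx == len(qnodes):
            best_score = partial
            best_map = dict(mapping)
            return
        u, ec = qnodes[idx]
        for t, tec in tnodes:
            if t in used:
                continue
            inc = ec_similarity(ec, tec, mu) + edge_increment(u, t)
            mapping[u] = t
            used.add(t)
            dfs(idx + 1, partial + inc)
            del mapping[u]
            used.discard(t)
        dfs(idx + 1, partial + d)  # delete u

    dfs(0, 0.0)
    return _result(query, best_map, best_score)


def _greedy_align(query: PathwayInstance, target: PathwayInstance,
                  params: AlignParams) -> AlignmentResult:
    """Deterministic greedy fallback for queries above the exact-search cap.

    Each query node (lexicographic order) takes the unused target node with
    the best EC similarity (lexicographic tie-break), or is deleted when
    deletion scores better; the full objective including topology penalties
    is then evaluated on the resulting mapping.
    """
    mu = params.ec_mismatch_penalty
    tnodes = sorted(target.nodes)
    used: set[str] = set()
    mapping: dict[str, str] = {}
    for u, ec in sorted(query.nodes):
        best_t, best_s = None, -float("inf")
        for t, tec in tnodes:
            if t in used:
                continue
            s = ec_similarity(ec, tec, mu)
            if s > best_s:
                best_t, best_s = t, s
        if best_t is not None and best_s >= params.deletion_score:
            mapping[u] = best_t
            used.add(best_t)
    score = score_mapping(query, target, mapping, params)
    return _result(query, mapping, score)


def align_pathways(query: PathwayInstance, target: PathwayInstance,
                   params: AlignParams = AlignParams()) -> AlignmentResult:
    """Align ``query`` against ``target`` (caller ensures |query| <= |target|).

    Exact for queries of up to ``params.exact_search_cap`` nodes, greedy
    beyond. Aligning an instance with an identical copy of itself returns
    the identity mapping with score 0.
    """
    if query.n_nodes == 0 or target.n_nodes == 0:
        raise ValidationError("cannot align an empty instance")
    if query.n_nodes > target.n_nodes:
        raise ValidationError(
            "query must not have more nodes than target; swap the arguments"
        )
    if _self_identical(query, target):
        return _result(query, {nid: nid for nid, _ in query.nodes}, 0.0)
    if query.n_nodes <= params.exact_search_cap:
        return _exact_align(query, target, params)
    return _greedy_align(query, target, params)


def brute_force_align(query: PathwayInstance, target: PathwayInstance,
                      params: AlignParams = AlignParams()) -> AlignmentResult:
    """Exhaustive enumeration of every partial injective map (test oracle).

    Refuses instances above 7 nodes. Independent of the branch-and-bound
    search path: generates each mapping outright and scores it with the
    plain objective evaluator.
    """
    if query.n_nodes > 7 or target.n_nodes > 7:
        raise ValidationError("brute_force_align is capped at 7 nodes per side")
    reach = _reachable(target, params.path_conservation)
    qids = [nid for nid, _ in sorted(query.nodes)]
    tids = [nid for nid, _ in sorted(target.nodes)]
    best: AlignmentResult | None = None
    from itertools import combinations
    for k in range(min(len(qids), len(tids)) + 1):
        for qsub in combinations(qids, k):
            for tperm in permutations(tids, k):
                mapping = dict(zip(qsub, tperm))
                s = score_mapping(query, target, mapping, params, reach)
                if best is None or s > best.score:
                    best = _result(query, mapping, s)
    assert best is not None
    return best
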