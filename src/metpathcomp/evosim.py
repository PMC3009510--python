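"""Simulate pathway-repertoire evolution along a known tree.

Provides ground truth for end-to-end validation: a random Yule tree over n
organisms, a root repertoire of m random pathway instances (small random
DAGs of 3-10 EC-labelled enzymes), and Poisson evolutionary events along
every branch:

* pathway loss / gain — flips presence (a regained pathway is a fresh
  random instance; the pipeline observes presence, not gain mechanism);
* EC mutation — rewrites one field of one enzyme's EC number;
* node indel — inserts or removes an enzyme;
* edge rewire — moves one reaction edge, preserving acyclicity.

Planted co-evolution: pathways may be partitioned into groups with a
coupling parameter rho; each loss/gain event fired by a group member is,
with probability rho, applied to every member of the group on that branch,
so group members share presence/absence history.

Event rates are per unit branch length per pathway, except EC mutation,
which is per enzyme node (larger pathways diverge faster, so different
pages lose similarity at different depths — a multi-resolution signal).
The default mutation rate (0.3 per node per unit length, with Yule trees
of height ~2 at the default splitting rate) leaves typical leaf pairs a
few EC field changes apart per pathway: deep enough to grade similarity,
shallow enough that alignment scores have not all collapsed to the
per-node deletion floor.

All randomness flows from one numpy Generator seeded by ``SimConfig.seed``;
equal seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .pathway_io import (
    InstanceTable,
    PathwayInstance,
    ValidationError,
    write_instance_table,
)
from .phylogeny import as_newick

__all__ = ["SimConfig", "SimTruth", "simulate_tree", "simulate_repertoires",
           "simulate", "write_simulation"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run (rates per unit branch length)."""

    n_organisms: int = 8
    m_pathways: int = 30
    seed: int = 0
    branch_length_mean: float = 1.0
    pathway_loss_rate: float = 0.05
    pathway_gain_rate: float = 0.02
    ec_mutation_rate: float = 0.3
    node_indel_rate: float = 0.1
    edge_rewire_rate: float = 0.1
    #: per-pathway group labels (length m) or None for no coupling
    coevolution_groups: Optional[tuple[int, ...]] = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_organisms < 3:
            raise ValidationError("need at least 3 organisms")
        if self.m_pathways < 1:
            raise ValidationError("need at least 1 pathway")
        for r in (self.pathway_loss_rate, self.pathway_gain_rate,
                  self.ec_mutation_rate, self.node_indel_rate,
                  self.edge_rewire_rate):
            if r < 0:
                raise ValidationError("rates must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [0, 1]")
        if (self.coevolution_groups is not None
                and len(self.coevolution_groups) != self.m_pathways):
            raise ValidationError("one group label per pathway is required")

    @classmethod
    def mutation_only(cls, n_organisms: int = 8, m_pathways: int = 30,
                      seed: int = 0, rate: float = 0.3) -> "SimConfig":
        """Divergence by EC mutation alone: presence never changes, so the
        tree signal is purely the graded similarity decay."""
        return cls(n_organisms=n_organisms, m_pathways=m_pathways, seed=seed,
                   pathway_loss_rate=0.0, pathway_gain_rate=0.0,
                   ec_mutation_rate=rate, node_indel_rate=0.0,
                   edge_rewire_rate=0.0)

    @classmethod
    def coevolving(cls, n_organisms: int = 8, m_pathways: int = 30,
                   seed: int = 0, rho: float = 0.9,
                   loss_rate: float = 0.025) -> "SimConfig":
        """Two planted pathway groups with strongly coupled, loss-dominated
        presence evolution.

        The per-pathway loss rate is kept low because coupling multiplies
        it: any member's event propagates to the whole group with
        probability rho, so a group of size g loses pathways at close to
        g * rate * rho per unit branch length. The default sits where a
        planted signal almost always survives: high enough that both
        groups rarely reach the leaves untouched, low enough that joint
        extinction of both groups (identical all-absent patterns) is
        rare.
        """
        groups = tuple(0 if i < m_pathways // 2 else 1
                       for i in range(m_pathways))
        return cls(n_organisms=n_organisms, m_pathways=m_pathways, seed=seed,
                   pathway_loss_rate=loss_rate, pathway_gain_rate=0.0,
                   ec_mutation_rate=0.3, node_indel_rate=0.0,
                   edge_rewire_rate=0.0, coevolution_groups=groups, rho=rho)


@dataclass
class SimTruth:
    """Ground truth of a simulation: tree, presence pattern, group labels."""

    tree: dendropy.Tree
    presence: np.ndarray          # n x m boolean, table order
    organisms: tuple[str, ...]
    pathways: tuple[str, ...]
    group_labels: Optional[tuple[int, ...]]


def simulate_tree(n: int, seed_or_rng: int | np.random.Generator = 0,
                  branch_length_mean: float = 1.0) -> dendropy.Tree:
    """A random Yule (pure-birth) tree.

    Lineages split at a constant per-lineage rate (1 / branch_length_mean),
    so with k extant lineages the wait to the next split is exponential
    with mean branch_length_mean / k, and the lineage that splits is chosen
    uniformly. A final exponential stretch with n lineages is appended so
    terminal branches have positive length. The result is ultrametric (all
    leaves contemporaneous), as a pure-birth process observed at one time
    point must be. Leaves are labelled O1..On in traversal order; the same
    seed always yields the same Newick string.
    """
    if n < 3:
        raise ValidationError("need at least 3 leaves")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    root = dendropy.Node()
    first, second = dendropy.Node(), dendropy.Node()
    root.add_child(first)
    root.add_child(second)
    # birth time of each extant lineage's pendant edge
    leaves = [first, second]
    birth = {first: 0.0, second: 0.0}
    now = 0.0
    while len(leaves) < n:
        k = len(leaves)
        now += float(rng.exponential(branch_length_mean / k))
        idx = int(rng.integers(k))
        parent = leaves.pop(idx)
        parent.edge.length = now - birth.pop(parent)
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            leaves.append(child)
            birth[child] = now
    now += float(rng.exponential(branch_length_mean / n))
    for leaf in leaves:
        leaf.edge.length = now - birth[leaf]
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            i += 1
            node.taxon = taxa.new_taxon(f"O{i}")
    tree.is_rooted = True
    return tree


# -- mutable working copy of an instance ------------------------------------

class _WorkingInstance:
    """Node list kept in topological order; edges always go forward."""

    def __init__(self, nodes: list[list[str]], edges: set[tuple[str, str]],
                 counter: int) -> None:
        self.nodes = nodes          # [[node_id, ec], ...]
        self.edges = edges
        self.counter = counter      # next fresh node id suffix

    @classmethod
    def random(cls, rng: np.random.Generator, n_nodes: tuple[int, int] = (3, 10),
               edge_prob: float = 0.35) -> "_WorkingInstance":
        n = int(rng.integers(n_nodes[0], n_nodes[1] + 1))
        nodes = [[f"n{i}", ".".join(str(rng.integers(1, 10)) for _ in range(4))]
                 for i in range(n)]
        edges = set()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < edge_prob:
                    edges.add((nodes[i][0], nodes[j][0]))
        return cls(nodes, edges, n)

    def copy(self) -> "_WorkingInstance":
        return _WorkingInstance([list(nd) for nd in self.nodes],
                                set(self.edges), self.counter)

    def mutate_ec(self, rng: np.random.Generator) -> None:
        nd = self.nodes[int(rng.integers(len(self.nodes)))]
        fields = nd[1].split(".")
        f = int(rng.integers(4))
        choices = [str(v) for v in range(1, 10) if str(v) != fields[f]]
        fields[f] = choices[int(rng.integers(len(choices)))]
        nd[1] = ".".join(fields)

    def indel(self, rng: np.random.Generator) -> None:
        if len(self.nodes) > 1 and rng.random() < 0.5:   # deletion
            idx = int(rng.integers(len(self.nodes)))
            nid = self.nodes[idx][0]
            del self.nodes[idx]
            self.edges = {(u, v) for u, v in self.edges
                          if u != nid and v != nid}
        else:                                            # insertion
            nid = f"n{self.counter}"
            self.counter += 1
            pos = int(rng.integers(len(self.nodes) + 1))
            ec = ".".join(str(rng.integers(1, 10)) for _ in range(4))
            self.nodes.insert(pos, [nid, ec])
            for i, (other, _) in enumerate(self.nodes):
                if other == nid or rng.random() >= 0.3:
                    continue
                self.edges.add((other, nid) if i < pos else (nid, other))

    def rewire(self, rng: np.random.Generator) -> None:
        if not self.edges:
            return
        order = {nd[0]: i for i, nd in enumerate(self.nodes)}
        candidates = [(u, v) for i, (u, _) in enumerate(self.nodes)
                      for j, (v, _) in enumerate(self.nodes)
                      if i < j and (u, v) not in self.edges]
        if not candidates:
            return
        old = sorted(self.edges)[int(rng.integers(len(self.edges)))]
        self.edges.discard(old)
        # forward edges only, so acyclicity is preserved by construction
        self.edges.add(candidates[int(rng.integers(len(candidates)))])

    def freeze(self, organism_id: str, pathway_id: str) -> PathwayInstance:
        order = {nd[0]: i for i, nd in enumerate(self.nodes)}
        edges = tuple(sorted(self.edges, key=lambda e: (order[e[0]], order[e[1]])))
        return PathwayInstance(organism_id, pathway_id,
                               tuple((nid, ec) for nid, ec in self.nodes), edges)


def simulate_repertoires(tree: dendropy.Tree, config: SimConfig
                         ) -> tuple[InstanceTable, SimTruth]:
    """Evolve a root repertoire down the tree; collect leaves into a table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = config.m_pathways
    pathways = tuple(f"p{k + 1:02d}" for k in range(m))
    groups = config.coevolution_groups
    members: dict[int, list[int]] = {}
    if groups is not None:
        for k, g in enumerate(groups):
            members.setdefault(g, []).append(k)

    root_state: list[Optional[_WorkingInstance]] = [
        _WorkingInstance.random(rng) for _ in range(m)
    ]

    leaf_states: dict[str, list[Optional[_WorkingInstance]]] = {}

    def evolve_branch(state: list[Optional[_WorkingInstance]],
                      length: float) -> list[Optional[_WorkingInstance]]:
        state = [s.copy() if s is not None else None for s in state]

        def apply_loss(k: int) -> None:
            state[k] = None

        def apply_gain(k: int) -> None:
            if state[k] is None:
                state[k] = _WorkingInstance.random(rng)

        for k in range(m):
            # presence events, possibly propagated to the whole group
            for kind, rate, apply in (
                ("loss", config.pathway_loss_rate, apply_loss),
                ("gain", config.pathway_gain_rate, apply_gain),
            ):
                if rate <= 0:
                    continue
                eligible = state[k] is not None if kind == "loss" else state[k] is None
                n_events = int(rng.poisson(rate * length))
                for _ in range(n_events):
                    if not eligible:
                        break
                    if groups is not None and rng.random() < config.rho:
                        for kk in members[groups[k]]:
                            apply(kk)
                    else:
                        apply(k)
                    eligible = False
        for k in range(m):
            inst = state[k]
            if inst is None:
                continue
            # EC mutation is per node: bigger pathways diverge faster
            n_mut = int(rng.poisson(config.ec_mutation_rate * length
                                    * len(inst.nodes)))
            for _ in range(n_mut):
                inst.mutate_ec(rng)
            for _ in range(int(rng.poisson(config.node_indel_rate * length))):
                inst.indel(rng)
            for _ in range(int(rng.poisson(config.edge_rewire_rate * length))):
                inst.rewire(rng)
        return state

    def walk(node: dendropy.Node,
             state: list[Optional[_WorkingInstance]]) -> None:
        for child in node.child_nodes():
            child_state = evolve_branch(state, child.edge.length or 0.0)
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
            else:
                walk(child, child_state)

    walk(tree.seed_node, root_state)

    organisms = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(organisms) != config.n_organisms:
        raise ValidationError(
            f"tree has {len(organisms)} leaves, config says "
            f"{config.n_organisms}"
        )
    table = InstanceTable(organisms, pathways)
    presence = np.zeros((len(organisms), m), dtype=bool)
    empty = []
    for oi, org in enumerate(organisms):
        state = leaf_states[org]
        if all(s is None for s in state):
            empty.append(org)
        for k, inst in enumerate(state):
            if inst is not None:
                presence[oi, k] = True
                table.set_cell(org, pathways[k], inst.freeze(org, pathways[k]))
    if empty:
        import logging
        logging.getLogger(__name__).warning(
            "organisms with no pathways left: %s", ", ".join(empty)
        )
    truth = SimTruth(tree, presence, organisms, pathways,
                     groups if groups is None else tuple(groups))
    return table, truth


def simulate(config: SimConfig) -> tuple[InstanceTable, SimTruth]:
    """Tree plus repertoires from one config (one seed governs both)."""
    tree = simulate_tree(
        config.n_organisms,
        np.random.default_rng(np.random.SeedSequence([config.seed, 0])),
        config.branch_length_mean,
    )
    table, truth = simulate_repertoires(tree, config)
    return table, truth


def write_simulation(table: InstanceTable, truth: SimTruth,
                     out_dir: str | Path) -> Path:
    """Emit manifest + instance files + truth/ (tree, presence, groups)."""
    out_dir = Path(out_dir)
    manifest = write_instance_table(table, out_dir)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    (truth_dir / "tree.nwk").write_text(as_newick(truth.tree))
    lines = ["organism\t" + "\t".join(truth.pathways)]
    for oi, org in enumerate(truth.organisms):
        lines.append(org + "\t" + "\t".join(
            "1" if truth.presence[oi, k] else "0"
            for k in range(len(truth.pathways))
        ))
    (truth_dir / "presence.tsv").write_text("\n".join(lines) + "\n")
    if truth.group_labels is not None:
        glines = ["pathway\tgroup"]
        glines += [f"{p}\t{g}" for p, g in zip(truth.pathways, truth.group_labels)]
        (truth_dir / "groups.tsv").write_text("\n".join(glines) + "\n")
    return manifest
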