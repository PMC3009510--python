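"""Input/output for pathway instances, similarity pages, matrices and trees.

On-disk formats
---------------
* Pathway instance: a small JSON object
  ``{"organism": str, "pathway": str, "nodes": [{"id": str, "ec": str}],
  "edges": [[str, str], ...]}`` describing a directed graph of EC-labelled
  enzymes.
* Instance table manifest: JSON
  ``{"organisms": [...], "pathways": [...], "cells": [{"organism": ...,
  "pathway": ..., "path": str or null}]}`` (``null`` marks the pathway as
  absent from that organism).
* Page: TSV with organism ids as first row and first column; cells hold a
  decimal score (<= 0) or one of the sentinel tokens ``ONE_MISSING`` /
  ``BOTH_MISSING``.
* Distance matrices: PHYLIP square format. Trees: Newick.

Organism and pathway orderings are taken verbatim from the manifest and are
never sorted implicitly; every matrix in the pipeline is indexed by that
order.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np


class MetPathCompError(Exception):
    """Base class for errors raised by this package."""


class FormatError(MetPathCompError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(MetPathCompError):
    """Parsed data violates a structural invariant."""


# ---------------------------------------------------------------------------
# Sentinels for missing page entries
# ---------------------------------------------------------------------------

class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __reduce__(self):  # singletons survive pickling
        return (_sentinel_lookup, (self._name,))


#: Page entry where the pathway exists in exactly one of the two organisms.
ONE_MISSING = _Sentinel("ONE_MISSING")
#: Page entry where the pathway exists in neither organism.
BOTH_MISSING = _Sentinel("BOTH_MISSING")

_SENTINELS = {"ONE_MISSING": ONE_MISSING, "BOTH_MISSING": BOTH_MISSING}


def _sentinel_lookup(name: str) -> _Sentinel:
    return _SENTINELS[name]


# Page entries are stored as a float matrix plus a small status code matrix.
STATUS_NUMERIC = 0
STATUS_ONE_MISSING = 1
STATUS_BOTH_MISSING = 2

_EC_FIELD = re.compile(r"^(\d+|-)$")


def validate_ec(ec: str) -> tuple[str, str, str, str]:
    """Check an EC label (four dot-separated fields, '-' wildcards allowed).

    Returns the four fields. Raises :class:`ValidationError` on malformed
    input such as ``"1.2.3"`` or ``"1.2.x.4"``.
    """
    parts = ec.split(".")
    if len(parts) != 4 or not all(_EC_FIELD.match(p) for p in parts):
        raise ValidationError(f"malformed EC number: {ec!r}")
    return tuple(parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Pathway instances and the organisms x pathways table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayInstance:
    """One pathway as it occurs in one organism: a directed enzyme graph.

    Nodes are (node_id, EC label) pairs; edges are ordered node-id pairs.
    """

    organism_id: str
    pathway_id: str
    nodes: tuple[tuple[str, str], ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValidationError(
                f"instance ({self.organism_id}, {self.pathway_id}) has no nodes"
            )
        ids = [nid for nid, _ in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"duplicate node ids in instance ({self.organism_id}, "
                f"{self.pathway_id})"
            )
        for _, ec in self.nodes:
            validate_ec(ec)
        declared = set(ids)
        for u, v in self.edges:
            if u not in declared or v not in declared:
                raise ValidationError(
                    f"edge ({u!r}, {v!r}) references an undeclared node in "
                    f"instance ({self.organism_id}, {self.pathway_id})"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ec_of(self, node_id: str) -> str:
        for nid, ec in self.nodes:
            if nid == node_id:
                return ec
        raise KeyError(node_id)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, ec in self.nodes:
            g.add_node(nid, ec=ec)
        g.add_edges_from(self.edges)
        return g


#: Marker for an (organism, pathway) cell with no pathway instance.
ABSENT = _Sentinel("ABSENT")
_SENTINELS["ABSENT"] = ABSENT


@dataclass
class InstanceTable:
    """The n x m grid of pathway instances over organisms and pathways.

    ``cell(i, k)`` is either a :class:`PathwayInstance` or :data:`ABSENT`.
    Orderings are fixed at construction and shared by every downstream
    matrix.
    """

    organisms: tuple[str, ...]
    pathways: tuple[str, ...]
    _cells: dict[tuple[str, str], PathwayInstance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.pathways = tuple(self.pathways)
        if len(self.organisms) < 2:
            raise ValidationError("an instance table needs at least 2 organisms")
        if len(self.pathways) < 1:
            raise ValidationError("an instance table needs at least 1 pathway")
        if len(set(self.organisms)) != len(self.organisms):
            raise ValidationError("duplicate organism ids")
        if len(set(self.pathways)) != len(self.pathways):
            raise ValidationError("duplicate pathway ids")

    @property
    def n_organisms(self) -> int:
        return len(self.organisms)

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    def set_cell(self, organism: str, pathway: str, inst: PathwayInstance) -> None:
        if organism not in self.organisms:
            raise ValidationError(f"unknown organism {organism!r}")
        if pathway not in self.pathways:
            raise ValidationError(f"unknown pathway {pathway!r}")
        key = (organism, pathway)
        if key in self._cells:
            raise ValidationError(f"duplicate cell for {key}")
        self._cells[key] = inst

    def cell(self, organism: str, pathway: str):
        """Return the instance at (organism, pathway), or ABSENT."""
        return self._cells.get((organism, pathway), ABSENT)

    def present(self, organism: str, pathway: str) -> bool:
        return (organism, pathway) in self._cells

    def presence_column(self, pathway: str) -> np.ndarray:
        """Boolean presence vector for one pathway, in organism order."""
        return np.array(
            [self.present(o, pathway) for o in self.organisms], dtype=bool
        )

    def presence_matrix(self) -> np.ndarray:
        """n x m boolean presence matrix in table order."""
        return np.column_stack([self.presence_column(p) for p in self.pathways])


# ---------------------------------------------------------------------------
# Pages
# ---------------------------------------------------------------------------

@dataclass
class Page:
    """All-against-all similarity matrix for one pathway over n organisms.

    ``scores[i, j]`` holds the alignment score where ``status[i, j]`` is
    :data:`STATUS_NUMERIC` and NaN elsewhere; ``status`` distinguishes
    numeric entries from the ONE_MISSING / BOTH_MISSING sentinels.
    """

    pathway_id: str
    organisms: tuple[str, ...]
    scores: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        n = len(self.organisms)
        self.scores = np.asarray(self.scores, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.scores.shape != (n, n) or self.status.shape != (n, n):
            raise ValidationError(
                f"page {self.pathway_id!r}: matrix shape does not match the "
                f"{n} organisms"
            )
        self.validate()

    @property
    def n(self) -> int:
        return len(self.organisms)

    def entry(self, i: int, j: int):
        """The (i, j) entry: a float score, ONE_MISSING or BOTH_MISSING."""
        s = self.status[i, j]
        if s == STATUS_NUMERIC:
            return float(self.scores[i, j])
        return ONE_MISSING if s == STATUS_ONE_MISSING else BOTH_MISSING

    def numeric_mask(self) -> np.ndarray:
        return self.status == STATUS_NUMERIC

    def validate(self) -> None:
        if not np.array_equal(self.status, self.status.T):
            raise ValidationError(f"page {self.pathway_id!r} is not symmetric")
        num = self.numeric_mask()
        sc = np.where(num, self.scores, 0.0)
        if not np.array_equal(sc, sc.T):
            raise ValidationError(
                f"page {self.pathway_id!r}: numeric entries are not symmetric"
            )
        if np.any(self.scores[num] > 0):
            raise ValidationError(
                f"page {self.pathway_id!r}: positive similarity score"
            )
        diag = np.diagonal(self.status)
        bad = (diag != STATUS_NUMERIC) & (diag != STATUS_BOTH_MISSING)
        if np.any(bad):
            raise ValidationError(
                f"page {self.pathway_id!r}: diagonal entries must be numeric "
                "(pathway present) or BOTH_MISSING (pathway absent)"
            )
        dn = diag == STATUS_NUMERIC
        if np.any(np.diagonal(self.scores)[dn] != 0.0):
            raise ValidationError(
                f"page {self.pathway_id!r}: self-alignment score must be 0"
            )

    @classmethod
    def from_entries(cls, pathway_id: str, organisms: Sequence[str],
                     entries: Sequence[Sequence[object]]) -> "Page":
        """Build a page from a nested list of floats and sentinels."""
        n = len(organisms)
        scores = np.full((n, n), np.nan)
        status = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for j in range(n):
                e = entries[i][j]
                if e is ONE_MISSING:
                    status[i, j] = STATUS_ONE_MISSING
                elif e is BOTH_MISSING:
                    status[i, j] = STATUS_BOTH_MISSING
                else:
                    scores[i, j] = float(e)  # type: ignore[arg-type]
        return cls(pathway_id, tuple(organisms), scores, status)


@dataclass
class PageStack:
    """The n x n x m stack of pages sharing one organism ordering."""

    organisms: tuple[str, ...]
    pathways: tuple[str, ...]
    pages: tuple[Page, ...]

    def __post_init__(self) -> None:
        self.organisms = tuple(self.organisms)
        self.pathways = tuple(self.pathways)
        self.pages = tuple(self.pages)
        if len(self.pages) != len(self.pathways):
            raise ValidationError("one page per pathway is required")
        for p in self.pages:
            if p.organisms != self.organisms:
                raise ValidationError(
                    f"page {p.pathway_id!r} does not share the stack's "
                    "organism ordering"
                )

    def page(self, k: int) -> Page:
        return self.pages[k]

    @property
    def m(self) -> int:
        return len(self.pathways)

    @property
    def n(self) -> int:
        return len(self.organisms)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_instance(path: str | Path) -> PathwayInstance:
    """Read one pathway instance from its JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("organism", "pathway", "nodes", "edges"):
        if key not in data:
            raise FormatError(f"{path}: missing key {key!r}")
    try:
        nodes = tuple((nd["id"], nd["ec"]) for nd in data["nodes"])
    except (TypeError, KeyError) as exc:
        raise FormatError(f"{path}: malformed 'nodes' entry") from exc
    edges = tuple((u, v) for u, v in data["edges"])
    return PathwayInstance(data["organism"], data["pathway"], nodes, edges)


def write_instance(inst: PathwayInstance, path: str | Path) -> None:
    data = {
        "organism": inst.organism_id,
        "pathway": inst.pathway_id,
        "nodes": [{"id": nid, "ec": ec} for nid, ec in inst.nodes],
        "edges": [[u, v] for u, v in inst.edges],
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_instance_table(manifest: str | Path) -> InstanceTable:
    """Materialize the full organisms x pathways table from a manifest.

    Cell paths are resolved relative to the manifest's directory.
    """
    manifest = Path(manifest)
    try:
        data = json.loads(manifest.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest}: not valid JSON ({exc})") from exc
    for key in ("organisms", "pathways", "cells"):
        if key not in data:
            raise FormatError(f"{manifest}: missing key {key!r}")
    table = InstanceTable(tuple(data["organisms"]), tuple(data["pathways"]))
    base = manifest.parent
    for cell in data["cells"]:
        org, pw, rel = cell["organism"], cell["pathway"], cell["path"]
        if rel is None:
            if not table.present(org, pw):
                # explicit absence; duplicates of an absent cell are harmless
                continue
            raise ValidationError(
                f"{manifest}: cell ({org}, {pw}) listed both present and absent"
            )
        p = base / rel
        if not p.exists():
            raise IOError(f"{manifest}: referenced file {p} does not exist")
        inst = read_instance(p)
        table.set_cell(org, pw, inst)
    return table


def write_instance_table(table: InstanceTable, out_dir: str | Path) -> Path:
    """Write all instances plus a manifest under ``out_dir``; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inst_dir = out_dir / "instances"
    inst_dir.mkdir(exist_ok=True)
    cells = []
    for oi, org in enumerate(table.organisms):
        for ki, pw in enumerate(table.pathways):
            inst = table.cell(org, pw)
            if inst is ABSENT:
                cells.append({"organism": org, "pathway": pw, "path": None})
            else:
                rel = f"instances/o{oi}_p{ki}.json"
                write_instance(inst, out_dir / rel)
                cells.append({"organism": org, "pathway": pw, "path": rel})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({
        "organisms": list(table.organisms),
        "pathways": list(table.pathways),
        "cells": cells,
    }, indent=1) + "\n")
    return manifest


def _format_score(x: float) -> str:
    return repr(float(x))  # shortest round-trip decimal


def write_page(page: Page, path: str | Path) -> None:
    """Serialize a page as TSV (header row/column of organism ids)."""
    lines = ["\t".join(("pathway:" + page.pathway_id,) + page.organisms)]
    for i, org in enumerate(page.organisms):
        row = [org]
        for j in range(page.n):
            e = page.entry(i, j)
            row.append(e._name if isinstance(e, _Sentinel) else _format_score(e))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_page(path: str | Path) -> Page:
    path = Path(path)
    lines = path.read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if not header or not header[0].startswith("pathway:"):
        raise FormatError(f"{path}: first header cell must be 'pathway:<id>'")
    pathway_id = header[0][len("pathway:"):]
    organisms = tuple(header[1:])
    n = len(organisms)
    if len(lines) != n + 1:
        raise FormatError(f"{path}: expected {n} data rows, found {len(lines) - 1}")
    entries: list[list[object]] = []
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n + 1:
            raise FormatError(f"{path}: row {i} has {len(cells) - 1} cells, expected {n}")
        if cells[0] != organisms[i]:
            raise FormatError(
                f"{path}: row label {cells[0]!r} does not match header "
                f"organism {organisms[i]!r}"
            )
        row: list[object] = []
        for tok in cells[1:]:
            if tok in ("ONE_MISSING", "BOTH_MISSING"):
                row.append(_SENTINELS[tok])
            else:
                try:
                    row.append(float(tok))
                except ValueError:
                    raise FormatError(f"{path}: unknown token {tok!r}") from None
        entries.append(row)
    return Page.from_entries(pathway_id, organisms, entries)


def write_phylip_matrix(ids: Sequence[str], matrix: np.ndarray,
                        path: str | Path) -> None:
    """Write a square distance matrix in PHYLIP format (relaxed names)."""
    matrix = np.asarray(matrix, dtype=float)
    lines = [f"    {len(ids)}"]
    for i, name in enumerate(ids):
        vals = "  ".join(_format_score(v) for v in matrix[i])
        lines.append(f"{name}  {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_matrix(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    path = Path(path)
    lines = path.read_text().strip().split("\n")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{path}: first line must be the taxon count") from None
    if len(lines) != n + 1:
        raise FormatError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    ids, rows = [], []
    for line in lines[1:]:
        parts = line.split()
        if len(parts) != n + 1:
            raise FormatError(f"{path}: row has {len(parts) - 1} values, expected {n}")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return tuple(ids), np.array(rows)


def random_instance(rng: np.random.Generator, organism_id: str,
                    pathway_id: str, n_nodes: int | None = None,
                    edge_prob: float = 0.35) -> PathwayInstance:
    """A random DAG instance with 3-10 EC-labelled nodes (testing helper)."""
    if n_nodes is None:
        n_nodes = int(rng.integers(3, 11))
    nodes = tuple(
        (f"n{i}", ".".join(str(rng.integers(1, 10)) for _ in range(4)))
        for i in range(n_nodes)
    )
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((f"n{i}", f"n{j}"))
    return PathwayInstance(organism_id, pathway_id, nodes, tuple(edges))
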