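import numpy as np
import pytest

from metpathcomp.pathway_io import (
    BOTH_MISSING,
    ONE_MISSING,
    InstanceTable,
    Page,
    PathwayInstance,
    random_instance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_instance(organism, pathway, ecs, edges=()):
    """Instance with nodes a, b, c... labelled by the given EC numbers."""
    names = "abcdefghij"
    nodes = tuple((names[i], ec) for i, ec in enumerate(ecs))
    return PathwayInstance(organism, pathway, nodes, tuple(edges))


@pytest.fixture
def chain_pair():
    """The two 2-node chains differing in one trailing EC field."""
    q = make_instance("O1", "p", ["1.1.1.1", "2.2.2.2"], [("a", "b")])
    t = make_instance("O2", "p", ["1.1.1.1", "2.2.2.3"], [("a", "b")])
    return q, t


@pytest.fixture
def toy_table(chain_pair):
    """3 organisms x 2 pathways; pathway p2 absent from O3."""
    q, t = chain_pair
    table = InstanceTable(("O1", "O2", "O3"), ("p1", "p2"))
    table.set_cell("O1", "p1", q)
    table.set_cell("O2", "p1", t)
    table.set_cell("O3", "p1", make_instance("O3", "p1", ["9.9.9.9"]))
    table.set_cell("O1", "p2", make_instance("O1", "p2", ["1.2.3.4"]))
    table.set_cell("O2", "p2", make_instance("O2", "p2", ["1.2.3.4"]))
    return table


@pytest.fixture
def page_3org():
    """The worked 3-organism page: O1/O2 similar, O3 far from both."""
    return Page.from_entries("pw", ("O1", "O2", "O3"), [
        [0.0, -1.0, -9.0],
        [-1.0, 0.0, -9.0],
        [-9.0, -9.0, 0.0],
    ])


def random_page(rng, n=4, pathway="p", absent=()):
    """Random symmetric page with the given organisms marked absent."""
    organisms = tuple(f"O{i+1}" for i in range(n))
    entries = [[None] * n for _ in range(n)]
    present = [o not in absent for o in organisms]
    for i in range(n):
        for j in range(i, n):
            if present[i] and present[j]:
                v = 0.0 if i == j else -float(rng.integers(0, 12))
            elif not present[i] and not present[j]:
                v = BOTH_MISSING
            else:
                v = ONE_MISSING
            entries[i][j] = entries[j][i] = v
    return Page.from_entries(pathway, organisms, entries)
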