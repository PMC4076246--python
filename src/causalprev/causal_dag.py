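"""Causal DAGs: d-separation, the backdoor criterion, and minimal
sufficient adjustment sets.

A :class:`CausalDag` is a directed acyclic graph over named nodes.
d-separation is decided by the moralized-ancestral-graph criterion: x and
y are d-separated given z iff they are disconnected in the undirected
moral graph of the ancestral subgraph of {x, y} ∪ z after deleting z.
A candidate set Z satisfies the backdoor criterion for (exposure X,
outcome Y) iff Z contains no descendant of X and Z blocks every path
into X that connects to Y — equivalently, X ⊥ Y | Z in the graph with
X's outgoing edges removed.  Minimal sufficient sets are found by
exhaustive search over subsets of non-descendants of X, keeping the
inclusion-minimal admissible ones.

Conditioning is not monotone: adding a collider (a node where two
arrowheads meet) to Z can open a previously blocked path, so a superset
of an admissible set need not be admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

__all__ = [
    "CausalDag",
    "AdjustmentQuery",
    "DagError",
    "is_acyclic",
    "d_separated",
    "backdoor_admissible",
    "minimal_adjustment_sets",
    "read_dag",
    "write_dag",
]


class DagError(ValueError):
    """Invalid graph structure or unknown node."""


@dataclass(frozen=True)
class CausalDag:
    """Immutable directed acyclic graph given by node names and
    (cause, effect) edge pairs.  Construction rejects self-loops, edges
    with undeclared endpoints, and directed cycles."""

    nodes: frozenset
    edges: frozenset

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple]):
        object.__setattr__(self, "nodes", frozenset(nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))
        for u, v in self.edges:
            if u == v:
                raise DagError(f"self-loop on node {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise DagError(f"edge ({u!r}, {v!r}) has an undeclared endpoint")
        if not is_acyclic(self):
            raise DagError("graph contains a directed cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def _require(self, *names: str) -> None:
        for name in names:
            if name not in self.nodes:
                raise DagError(f"unknown node {name!r}")

    def descendants(self, node: str) -> set:
        """Strict descendants of ``node``."""
        self._require(node)
        return set(nx.descendants(self.to_networkx(), node))


@dataclass(frozen=True)
class AdjustmentQuery:
    """A backdoor-admissibility question: is ``candidate_set`` sufficient
    to adjust for confounding of ``exposure`` on ``outcome``?"""

    exposure: str
    outcome: str
    candidate_set: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "candidate_set", frozenset(self.candidate_set))
        if self.exposure == self.outcome:
            raise DagError("exposure and outcome must differ")
        if self.exposure in self.candidate_set or self.outcome in self.candidate_set:
            raise DagError("candidate_set must exclude exposure and outcome")


def is_acyclic(dag: CausalDag) -> bool:
    """True iff the edge set contains no directed cycle."""
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    return nx.is_directed_acyclic_graph(g)


def _moral_disconnected(g: nx.DiGraph, x: str, y: str, z: set) -> bool:
    """x–y disconnected given z in the moralized ancestral graph of g."""
    keep = {x, y} | z
    ancestral = set(keep)
    for node in keep:
        ancestral |= nx.ancestors(g, node)
    sub = g.subgraph(ancestral)
    moral = nx.Graph()
    moral.add_nodes_from(sub.nodes)
    moral.add_edges_from(sub.edges)
    for node in sub.nodes:  # marry parents of every common child
        parents = list(sub.predecessors(node))
        moral.add_edges_from(combinations(parents, 2))
    moral.remove_nodes_from(z)
    return not nx.has_path(moral, x, y)


def d_separated(dag: CausalDag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """True iff every path between ``x`` and ``y`` is blocked given ``z``.

    A path is blocked when it contains a chain or fork node that is
    conditioned on, or a collider such that neither it nor any of its
    descendants is conditioned on.
    """
    z = set(z)
    dag._require(x, y, *z)
    if x in z or y in z:
        raise DagError("x and y must not be members of z")
    return _moral_disconnected(dag.to_networkx(), x, y, z)


def backdoor_admissible(dag: CausalDag, query: AdjustmentQuery) -> bool:
    """Decide the backdoor criterion for ``query`` on ``dag``.

    The candidate set must contain no descendant of the exposure, and
    conditioning on it must block every backdoor path (path whose first
    edge points into the exposure) from exposure to outcome.
    """
    x, y, z = query.exposure, query.outcome, set(query.candidate_set)
    dag._require(x, y, *z)
    if z & dag.descendants(x):
        return False
    g = dag.to_networkx()
    # removing X's outgoing edges leaves exactly the paths that start
    # with an arrow into X
    g.remove_edges_from(list(g.out_edges(x)))
    return _moral_disconnected(g, x, y, z)


def minimal_adjustment_sets(dag: CausalDag, exposure: str, outcome: str) -> list:
    """All inclusion-minimal backdoor-admissible sets for
    (``exposure``, ``outcome``), sorted by size then lexicographically.

    Exhaustive search over subsets of nodes that are neither the exposure,
    the outcome, nor descendants of the exposure; intended for the small
    graphs used in identification arguments.
    """
    dag._require(exposure, outcome)
    candidates = sorted(dag.nodes - {exposure, outcome} - dag.descendants(exposure))
    admissible: list[frozenset] = []
    for size in range(len(candidates) + 1):
        for combo in combinations(candidates, size):
            s = frozenset(combo)
            if any(prev <= s for prev in admissible):
                continue  # a subset is already admissible: not minimal
            if backdoor_admissible(dag, AdjustmentQuery(exposure, outcome, s)):
                admissible.append(s)
    return sorted(admissible, key=lambda s: (len(s), sorted(s)))


# ---------------------------------------------------------------------------
# edge-list text format: one "cause -> effect" per line, '#' comments,
# bare names declare isolated nodes

def read_dag(path) -> CausalDag:
    """Parse a DAG from the edge-list text format."""
    nodes, edges = set(), set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" in line:
                left, _, right = line.partition("->")
                u, v = left.strip(), right.strip()
                if not u or not v:
                    raise DagError(f"{path}:{lineno}: malformed edge {line!r}")
                nodes |= {u, v}
                edges.add((u, v))
            else:
                nodes.add(line)
    return CausalDag(nodes, edges)


def write_dag(dag: CausalDag, path) -> None:
    """Write a DAG in the edge-list text format (sorted, diffable)."""
    with_edges = {u for u, _ in dag.edges} | {v for _, v in dag.edges}
    with open(path, "w") as fh:
        for node in sorted(dag.nodes - with_edges):
            fh.write(f"{node}\n")
        for u, v in sorted(dag.edges):
            fh.write(f"{u} -> {v}\n")
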