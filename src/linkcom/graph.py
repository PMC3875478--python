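"""Graph ingestion and the link-space matrices.

A :class:`Network` is an undirected simple graph whose edges carry a
canonical 1-based *link index* given by first-appearance order.  Everything
downstream — the partition-density objective, the exact solvers and the
genetic algorithm — works in link space, through three matrices derived
here:

``B``
    the *incidence matrix* (links x nodes): row *j* has a 1 at each of the
    two endpoints of link *j*.
``E = B @ B.T``
    the *link adjacency matrix*: off-diagonal entry 1 when two links share
    a node, diagonal 2.
``W = B @ D @ B.T``
    the *weighted link adjacency matrix*, with ``D`` the diagonal matrix of
    inverse node degrees.  Its off-diagonal entry for two links meeting at
    node *v* is ``1/deg(v)`` — the probability that a random walker steps
    from one link to the other across their common node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_edge_list",
    "read_gml",
    "incidence_matrix",
    "link_adjacency",
    "inverse_degree_matrix",
    "weighted_link_adjacency",
    "write_edge_list",
]


@dataclass(frozen=True)
class Network:
    """An undirected simple graph with deterministic node and link order.

    Parameters
    ----------
    nodes
        Node labels in first-appearance order.
    edges
        Unordered node pairs in first-appearance order; position ``j``
        (0-based) is link ``j + 1`` in all external, 1-based reports.
    """

    nodes: tuple
    edges: tuple
    _index: dict = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {u: i for i, u in enumerate(self.nodes)})
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in self._index or v not in self._index:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint not in nodes")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def m(self) -> int:
        """Number of links."""
        return len(self.edges)

    def node_index(self, label) -> int:
        return self._index[label]

    def degrees(self) -> np.ndarray:
        """Degree of every node, in node order."""
        deg = np.zeros(self.n, dtype=np.int64)
        for u, v in self.edges:
            deg[self._index[u]] += 1
            deg[self._index[v]] += 1
        return deg

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "Network":
        """Build a network from an iterable of node-label pairs.

        Node and link order follow first appearance; duplicate edges and
        self-loops raise.
        """
        nodes: list = []
        index: dict = {}
        edge_list: list = []
        for u, v in edges:
            for w in (u, v):
                if w not in index:
                    index[w] = len(nodes)
                    nodes.append(w)
            edge_list.append((u, v))
        return cls(tuple(nodes), tuple(edge_list))

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "Network":
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("only simple undirected graphs are supported")
        net = cls.from_edges(graph.edges())
        if graph.number_of_nodes() != net.n:
            raise ValueError("graph has isolated nodes; remove them first")
        return net

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def edge(self, link_id: int) -> tuple:
        """Endpoints of 1-based link ``link_id``."""
        return self.edges[link_id - 1]


def read_edge_list(source) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    ``source`` may be a path, a text stream, or a string containing the
    edge list itself (detected by the presence of a newline).  Lines
    starting with ``#`` are ignored; tokens beyond the first two (e.g.
    weights) are ignored with a warning; duplicate edges are collapsed
    with a warning; self-loops are an error naming the offending line.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    nodes: list = []
    index: dict = {}
    edges: list = []
    seen: set = set()
    warned_extra = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"line {lineno}: expected two node labels, got {line!r}")
        if len(tokens) > 2 and not warned_extra:
            logger.warning(
                "edge list has extra columns (weights?); they are ignored"
            )
            warned_extra = True
        u, v = tokens[0], tokens[1]
        if u == v:
            raise ValueError(f"line {lineno}: self-loop on node {u!r}")
        key = frozenset((u, v))
        if key in seen:
            logger.warning("line %d: duplicate edge (%s, %s) collapsed", lineno, u, v)
            continue
        seen.add(key)
        for w in (u, v):
            if w not in index:
                index[w] = len(nodes)
                nodes.append(w)
        edges.append((u, v))
    if not edges:
        raise ValueError("no edges")
    return Network(tuple(nodes), tuple(edges))


def read_gml(path) -> Network:
    """Read a GML file; only id/label/edge fields are honored."""
    graph = nx.read_gml(path, label="label")
    return Network.from_networkx(nx.Graph(graph))


def write_edge_list(net: Network, target) -> None:
    """Write ``net`` as a plain edge list (one ``u v`` pair per line)."""
    text = "\n".join(f"{u} {v}" for u, v in net.edges) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)


def incidence_matrix(net: Network) -> np.ndarray:
    """Links x nodes binary incidence matrix ``B``.

    Row *j* has a 1 exactly at the two endpoints of link *j*; column sums
    reproduce the degree sequence.
    """
    B = np.zeros((net.m, net.n), dtype=np.int64)
    for j, (u, v) in enumerate(net.edges):
        B[j, net.node_index(u)] = 1
        B[j, net.node_index(v)] = 1
    return B


def link_adjacency(B: np.ndarray) -> np.ndarray:
    """Link adjacency matrix ``E = B @ B.T`` (diagonal 2, off-diagonal 0/1)."""
    return B @ B.T


def inverse_degree_matrix(net: Network) -> np.ndarray:
    """Diagonal matrix of inverse node degrees.

    Raises if any node is isolated (degree zero).
    """
    deg = net.degrees()
    if np.any(deg == 0):
        bad = [net.nodes[i] for i in np.flatnonzero(deg == 0)]
        raise ValueError(f"isolated node(s): {bad}")
    return np.diag(1.0 / deg)


def weighted_link_adjacency(B: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Weighted link adjacency ``W = B @ D @ B.T``.

    The off-diagonal entry for two links sharing node *v* is ``1/deg(v)``:
    the random-walk transition weight across the common node.
    """
    if B.shape[1] != D.shape[0]:
        raise ValueError("incidence and degree matrices refer to different networks")
    return B @ D @ B.T
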