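"""Deterministic generators for the clique-based validation families.

Every generator returns a :class:`PlantedNetwork`: the graph, the planted
ground-truth link partition, and the planted overlapping nodes.  The
families are unions of cliques glued at single nodes, at shared edges or
shared triangles, rings and trees of heterogeneous cliques, and the
double-star tree that motivates the density objective.  All constructions
are deterministic — identical arguments give identical edge lists — so
test fixtures need no stored data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, List, Sequence

import networkx as nx

from .density import LinkPartition, partition_density
from .graph import Network

__all__ = [
    "PlantedNetwork",
    "union_of_cliques",
    "five_clique_union",
    "two_cliques_shared_edge",
    "two_cliques_shared_triangle",
    "ring_of_cliques",
    "overlapping_ring_of_cliques",
    "tree_of_cliques",
    "star_tree_of_cliques",
    "double_star",
    "karate_club",
]


@dataclass(frozen=True)
class PlantedNetwork:
    """A benchmark graph with its planted ground truth."""

    network: Network
    partition: LinkPartition
    overlapping_nodes: FrozenSet
    planted_density: float

    @property
    def overlapping_links(self) -> FrozenSet[int]:
        """1-based ids of links planted in more than one community."""
        return frozenset(
            j for j, ks in self.partition.assignment.items() if len(ks) > 1
        )


class _Builder:
    """Accumulates clique edge sets with first-appearance link indexing."""

    def __init__(self):
        self.edges: List[tuple] = []
        self.edge_ids: dict = {}
        self.communities: dict = {}

    def add_clique(self, label: int, nodes: Sequence, allow_shared=True):
        links = set()
        for u, v in combinations(nodes, 2):
            key = frozenset((u, v))
            if key not in self.edge_ids:
                self.edge_ids[key] = len(self.edges) + 1
                self.edges.append((u, v))
            elif not allow_shared:
                raise ValueError(
                    f"cliques share edge ({u}, {v}); use a shared-overlap generator"
                )
            links.add(self.edge_ids[key])
        self.communities[label] = links

    def planted(self, overlapping_nodes) -> PlantedNetwork:
        net = Network.from_edges(self.edges)
        partition = LinkPartition.from_communities(
            self.communities, net.m, K=len(self.communities)
        )
        density = partition_density(net, partition).D
        return PlantedNetwork(net, partition, frozenset(overlapping_nodes), density)


def union_of_cliques(node_lists: Sequence[Sequence]) -> PlantedNetwork:
    """Union of complete graphs on the given node lists.

    The lists may share nodes but must not share edges (two lists with two
    or more common nodes would); use the shared-edge/-triangle generators
    for that.  Planted communities are the per-clique link sets; planted
    overlapping nodes are those in more than one list.
    """
    if any(len(nodes) < 2 for nodes in node_lists):
        raise ValueError("each clique needs at least 2 nodes")
    for a, b in combinations(range(len(node_lists)), 2):
        shared = set(node_lists[a]) & set(node_lists[b])
        if len(shared) >= 2:
            raise ValueError(
                f"cliques {a} and {b} share edge(s) on nodes {sorted(shared)}; "
                "use a shared-overlap generator"
            )
    builder = _Builder()
    seen_counts: dict = {}
    for label, nodes in enumerate(node_lists, start=1):
        builder.add_clique(label, nodes)
        for u in nodes:
            seen_counts[u] = seen_counts.get(u, 0) + 1
    overlapping = [u for u, c in seen_counts.items() if c > 1]
    return builder.planted(overlapping)


def five_clique_union() -> PlantedNetwork:
    """The five-clique benchmark: cliques on {1..5}, {7..11}, {12..15},
    {16..18} and {1,7,12,16}, overlapping at nodes 1, 7, 12 and 16."""
    return union_of_cliques(
        [
            list(range(1, 6)),
            list(range(7, 12)),
            list(range(12, 16)),
            list(range(16, 19)),
            [1, 7, 12, 16],
        ]
    )


def two_cliques_shared_edge(n1: int = 4, n2: int = 3) -> PlantedNetwork:
    """Two cliques sharing exactly the edge (1, 2).

    The planted (overlapping) partition puts the shared link in both
    communities, so each community is complete and the density is 1.
    """
    if n1 < 3 or n2 < 3:
        raise ValueError("clique sizes must be >= 3 to share an edge properly")
    clique1 = list(range(1, n1 + 1))
    clique2 = [1, 2] + list(range(n1 + 1, n1 + n2 - 1))
    builder = _Builder()
    builder.add_clique(1, clique1)
    builder.add_clique(2, clique2)
    return builder.planted({1, 2})


def two_cliques_shared_triangle(n1: int = 5, n2: int = 4) -> PlantedNetwork:
    """Two cliques whose overlap is the triangle on nodes {1, 2, 3}; the
    three shared links are planted in both communities."""
    if n1 < 4 or n2 < 4:
        raise ValueError("clique sizes must be >= 4 to share a triangle properly")
    clique1 = list(range(1, n1 + 1))
    clique2 = [1, 2, 3] + list(range(n1 + 1, n1 + n2 - 2))
    builder = _Builder()
    builder.add_clique(1, clique1)
    builder.add_clique(2, clique2)
    return builder.planted({1, 2, 3})


def ring_of_cliques(sizes: Sequence[int]) -> PlantedNetwork:
    """Ring of cliques, consecutive cliques sharing exactly one node.

    Shared nodes are labelled 1..C (C cliques); private nodes follow.
    The planted per-clique partition is disjoint with density 1; the C
    shared nodes are the planted overlapping nodes.
    """
    sizes = list(sizes)
    C = len(sizes)
    if C < 3:
        raise ValueError("a ring needs at least 3 cliques")
    if any(s < 3 for s in sizes):
        raise ValueError("clique sizes must be >= 3")
    # shared node s_c sits between clique c and clique c+1 (mod C)
    next_label = C + 1
    builder = _Builder()
    for c in range(C):
        prev_shared = c if c > 0 else C  # s_{c-1}, with s_{-1} = s_{C-1} = C
        own_shared = c + 1
        privates = list(range(next_label, next_label + sizes[c] - 2))
        next_label += sizes[c] - 2
        builder.add_clique(c + 1, [prev_shared, own_shared] + privates)
    return builder.planted(range(1, C + 1))


def overlapping_ring_of_cliques(
    sizes: Sequence[int], overlap_sizes: Sequence[int] | int
) -> PlantedNetwork:
    """Ring of cliques in which consecutive cliques share a small clique.

    ``overlap_sizes[c]`` nodes (>= 2) are shared between clique c and
    clique c+1; the links inside each shared block are planted in both
    adjacent communities, so every community is complete and the planted
    (overlapping) density is 1.
    """
    sizes = list(sizes)
    C = len(sizes)
    if C < 3:
        raise ValueError("a ring needs at least 3 cliques")
    if isinstance(overlap_sizes, int):
        overlap_sizes = [overlap_sizes] * C
    overlaps = list(overlap_sizes)
    if len(overlaps) != C:
        raise ValueError("need one overlap size per adjacent clique pair")
    if any(o < 2 for o in overlaps):
        raise ValueError("overlap blocks must have >= 2 nodes (a shared link)")
    for c in range(C):
        if overlaps[c - 1] + overlaps[c] > sizes[c]:
            raise ValueError(
                f"clique {c + 1} (size {sizes[c]}) cannot host overlap blocks "
                f"of sizes {overlaps[c - 1]} and {overlaps[c]}"
            )
    # shared blocks first: block c (between cliques c and c+1) gets
    # overlap_sizes[c] consecutive labels
    blocks = []
    next_label = 1
    for o in overlaps:
        blocks.append(list(range(next_label, next_label + o)))
        next_label += o
    builder = _Builder()
    for c in range(C):
        n_priv = sizes[c] - overlaps[c - 1] - overlaps[c]
        privates = list(range(next_label, next_label + n_priv))
        next_label += n_priv
        builder.add_clique(c + 1, blocks[c - 1] + privates + blocks[c])
    overlapping = [u for block in blocks for u in block]
    return builder.planted(overlapping)


def tree_of_cliques(parent: Sequence, sizes: Sequence[int]) -> PlantedNetwork:
    """Tree of cliques, each child sharing one node with its parent.

    ``parent[i]`` is the 0-based index of clique i's parent (None for the
    root, which must come first).  Attachment points cycle through the
    parent clique's nodes, so siblings attach at distinct nodes while the
    parent has room.
    """
    parent = list(parent)
    sizes = list(sizes)
    if len(parent) != len(sizes):
        raise ValueError("parent and sizes must have equal length")
    if parent[0] is not None:
        raise ValueError("clique 0 must be the root (parent None)")
    if any(s < 3 for s in sizes):
        raise ValueError("clique sizes must be >= 3")
    for i, p in enumerate(parent[1:], start=1):
        if p is None or not 0 <= p < i:
            raise ValueError("parent indices must encode a tree (parent[i] < i)")
    clique_nodes: List[List[int]] = []
    child_count = [0] * len(sizes)
    next_label = 1
    overlapping = set()
    builder = _Builder()
    for i, (p, s) in enumerate(zip(parent, sizes)):
        if p is None:
            nodes = list(range(next_label, next_label + s))
            next_label += s
        else:
            attach = clique_nodes[p][child_count[p] % len(clique_nodes[p])]
            child_count[p] += 1
            overlapping.add(attach)
            nodes = [attach] + list(range(next_label, next_label + s - 1))
            next_label += s - 1
        clique_nodes.append(nodes)
        builder.add_clique(i + 1, nodes)
    return builder.planted(overlapping)


def star_tree_of_cliques(n_cliques: int = 5, size: int = 4) -> PlantedNetwork:
    """Star tree: one central clique with ``n_cliques - 1`` child cliques,
    each sharing one node with the center."""
    if n_cliques < 2:
        raise ValueError("need at least 2 cliques")
    return tree_of_cliques([None] + [0] * (n_cliques - 1), [size] * n_cliques)


def double_star(k1: int = 3, k2: int = 3) -> PlantedNetwork:
    """Two star graphs sharing one leaf — the tree that motivates the
    density objective.

    Centers are nodes 1 and 2; node 3 is the shared leaf (the planted
    overlapping node).  The planted partition colors each star's links as
    one community.  Being a tree, every partition has Ahn baseline
    density 0, while the new density strictly prefers this planted
    two-star partition.
    """
    if k1 < 2 or k2 < 2:
        raise ValueError("each star needs at least 2 leaves")
    star1_leaves = [3] + list(range(4, 4 + k1 - 1))
    star2_leaves = [3] + list(range(4 + k1 - 1, 4 + k1 - 1 + k2 - 1))
    edges = [(1, leaf) for leaf in star1_leaves] + [(2, leaf) for leaf in star2_leaves]
    net = Network.from_edges(edges)
    labels = [1] * k1 + [2] * k2
    partition = LinkPartition.from_labels(labels, K=2)
    density = partition_density(net, partition).D
    return PlantedNetwork(net, partition, frozenset({3}), density)


def karate_club() -> Network:
    """Zachary's karate club (34 nodes, 78 edges), nodes relabelled 1..34."""
    g = nx.karate_club_graph()
    return Network.from_edges((u + 1, v + 1) for u, v in g.edges())
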