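"""Exact optimization of the two integer-programming formulations.

Model-1 assigns every link to exactly one of at most K communities;
Model-2 assigns every link to at least one community, with a link in
several communities counted once per membership in the objective.  Both
maximize the (new) link partition density.

The objective is a nonlinear ratio, so a linear MILP solver does not
apply; instead the solvers here are exact by construction:

* **Phase 1 — clique search.**  The partition density is at most 1, with
  equality iff every non-empty community's link set is a complete graph
  on its induced nodes.  A complete backtracking search over
  clique-structured assignments therefore either produces a provably
  optimal density-1 solution or proves that the optimum is below 1.
  This phase scales to the clique-union benchmark networks regardless of
  link count.
* **Phase 2 — exhaustive enumeration.**  When no density-1 assignment
  exists, all assignments are enumerated with community-label symmetry
  quotiented out (restricted-growth order: a new label may be used only
  after all smaller labels have appeared).  This is exponential and is
  capped by ``max_links``; beyond the cap the genetic algorithm is the
  intended tool.

Ties are broken toward the first solution in canonical enumeration order
(links in index order; labels in first-use order; fewer memberships first
for Model-2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .density import LinkPartition, partition_density
from .graph import Network, incidence_matrix

__all__ = [
    "ModelSolution",
    "NetworkTooLarge",
    "check_model1_feasible",
    "check_model2_feasible",
    "solve_model1",
    "solve_model2",
    "select_K",
]

_EPS = 1e-12


class NetworkTooLarge(ValueError):
    """Raised when exhaustive enumeration would be needed but the network
    exceeds ``max_links``; use the genetic algorithm instead."""


@dataclass(frozen=True)
class ModelSolution:
    """An optimal link assignment found by exact search."""

    partition: LinkPartition
    density: float
    model: str
    K: int
    enumeration_size: int


def check_model1_feasible(net: Network, x: np.ndarray, y: np.ndarray) -> bool:
    """Check the Model-1 constraints for a candidate (x, y).

    ``x`` is the m x K binary link-membership matrix; ``y`` the n x K
    node-membership matrix.  Feasible iff every link is in exactly one
    community and y marks node i in community k exactly when some link
    incident to i is in k.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != net.m or y.shape[0] != net.n or x.shape[1] != y.shape[1]:
        raise ValueError("dimension mismatch between network, x and y")
    if not np.array_equal(x.sum(axis=1), np.ones(net.m, dtype=x.dtype)):
        return False
    B = incidence_matrix(net)
    return np.array_equal(y != 0, (B.T @ x) > 0)


def check_model2_feasible(net: Network, x: np.ndarray, y: np.ndarray) -> bool:
    """Model-2 analogue: every link in at least one community."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != net.m or y.shape[0] != net.n or x.shape[1] != y.shape[1]:
        raise ValueError("dimension mismatch between network, x and y")
    if np.any(x.sum(axis=1) < 1):
        return False
    B = incidence_matrix(net)
    return np.array_equal(y != 0, (B.T @ x) > 0)


def _adjacency(net: Network):
    adj = {u: set() for u in net.nodes}
    edge_index = {}
    for j, (u, v) in enumerate(net.edges):
        adj[u].add(v)
        adj[v].add(u)
        edge_index[frozenset((u, v))] = j
    return adj, edge_index


def _clique_partition_search(net: Network, K: int):
    """Complete search for a partition of the links into at most K
    communities each forming a complete graph; returns 0-based labels or
    None.  Any hit has partition density exactly 1 and is optimal."""
    m = net.m
    adj, edge_index = _adjacency(net)
    assignment = [-1] * m
    comm_nodes: list = []  # node set per community
    comm_links: list = []

    def feasible(c: int, j: int, u, v) -> bool:
        for w in comm_nodes[c]:
            if w == u or w == v:
                continue
            if u not in adj[w] or v not in adj[w]:
                return False
            for pair in ((w, u), (w, v)):
                ei = edge_index[frozenset(pair)]
                if ei < j and assignment[ei] != c:
                    return False
        return True

    def place(c: int, j: int, u, v):
        added = [w for w in (u, v) if w not in comm_nodes[c]]
        comm_nodes[c].update(added)
        comm_links[c].add(j)
        assignment[j] = c
        return added

    def unplace(c: int, j: int, added):
        comm_nodes[c].difference_update(added)
        comm_links[c].discard(j)
        assignment[j] = -1

    def rec(j: int) -> bool:
        if j == m:
            return all(
                len(links) == len(nodes) * (len(nodes) - 1) // 2
                for nodes, links in zip(comm_nodes, comm_links)
            )
        u, v = net.edges[j]
        forced = [c for c in range(len(comm_nodes))
                  if u in comm_nodes[c] and v in comm_nodes[c]]
        if len(forced) > 1:
            return False  # link j would have to be in two communities
        if forced:
            c = forced[0]
            added = place(c, j, u, v)
            if rec(j + 1):
                return True
            unplace(c, j, added)
            return False
        for c in range(len(comm_nodes)):
            if feasible(c, j, u, v):
                added = place(c, j, u, v)
                if rec(j + 1):
                    return True
                unplace(c, j, added)
        if len(comm_nodes) < K:
            comm_nodes.append({u, v})
            comm_links.append({j})
            assignment[j] = len(comm_nodes) - 1
            if rec(j + 1):
                return True
            comm_nodes.pop()
            comm_links.pop()
            assignment[j] = -1
        return False

    return list(assignment) if rec(0) else None


def _clique_cover_search(net: Network, K: int):
    """Complete search for a cover of the links by at most K communities,
    each a complete graph, links allowed in several communities (the
    density-1 case of Model-2).  Returns a list of 0-based label sets or
    None.  Membership is forced whenever both endpoints of a link already
    lie in a community (otherwise that community could never be complete).
    """
    m = net.m
    adj, edge_index = _adjacency(net)
    assignment: list = [None] * m
    comm_nodes: list = []
    comm_links: list = []

    def feasible(c: int, j: int, u, v) -> bool:
        for w in comm_nodes[c]:
            if w == u or w == v:
                continue
            if u not in adj[w] or v not in adj[w]:
                return False
            for pair in ((w, u), (w, v)):
                ei = edge_index[frozenset(pair)]
                if ei < j and c not in assignment[ei]:
                    return False
        return True

    def rec(j: int) -> bool:
        if j == m:
            return all(
                len(links) == len(nodes) * (len(nodes) - 1) // 2
                for nodes, links in zip(comm_nodes, comm_links)
            )
        u, v = net.edges[j]
        ncomm = len(comm_nodes)
        forced = [c for c in range(ncomm)
                  if u in comm_nodes[c] and v in comm_nodes[c]]
        optional = [c for c in range(ncomm)
                    if c not in forced and feasible(c, j, u, v)]
        # choices: subset of optional communities + t brand-new ones,
        # fewest extra memberships first (canonical tie-break).
        choices = []
        for size in range(len(optional) + 1):
            for subset in itertools.combinations(optional, size):
                for t in range(K - ncomm + 1):
                    if forced or subset or t:
                        choices.append((subset, t))
        choices.sort(key=lambda st: (len(st[0]) + st[1], st[0]))
        for subset, t in choices:
            chosen = list(forced) + list(subset)
            added_nodes = []
            for c in chosen:
                added = [w for w in (u, v) if w not in comm_nodes[c]]
                comm_nodes[c].update(added)
                comm_links[c].add(j)
                added_nodes.append(added)
            new_ids = []
            for _ in range(t):
                comm_nodes.append({u, v})
                comm_links.append({j})
                new_ids.append(len(comm_nodes) - 1)
            assignment[j] = set(chosen) | set(new_ids)
            if rec(j + 1):
                return True
            assignment[j] = None
            for _ in new_ids:
                comm_nodes.pop()
                comm_links.pop()
            for c, added in zip(chosen, added_nodes):
                comm_nodes[c].difference_update(added)
                comm_links[c].discard(j)
        return False

    return [set(s) for s in assignment] if rec(0) else None


def _evaluate(counts, node_counts, mode: str) -> float:
    """Density from incremental per-community (m_c, node-multiset) state."""
    num = 0.0
    total = 0
    terms = 0
    mean_sum = 0.0
    for m_c, nodes in zip(counts, node_counts):
        if m_c == 0:
            continue
        n_c = len(nodes)
        d = 2.0 * m_c / (n_c * (n_c - 1))
        num += m_c * d
        total += m_c
        mean_sum += d
        terms += 1
    if mode == "link-weighted":
        return num / total
    return mean_sum / terms


def _enumerate_model1(net: Network, K: int, mode: str):
    """Restricted-growth enumeration of all disjoint assignments with at
    most K communities; returns (best labels, best density, leaf count)."""
    m = net.m
    edges = net.edges
    counts = [0] * K
    node_counts = [dict() for _ in range(K)]
    labels = [0] * m
    best = {"labels": None, "density": -1.0, "leaves": 0}

    def add(c, u, v):
        counts[c] += 1
        for w in (u, v):
            node_counts[c][w] = node_counts[c].get(w, 0) + 1

    def remove(c, u, v):
        counts[c] -= 1
        for w in (u, v):
            node_counts[c][w] -= 1
            if node_counts[c][w] == 0:
                del node_counts[c][w]

    def rec(j: int, used: int):
        if j == m:
            best["leaves"] += 1
            d = _evaluate(counts, node_counts, mode)
            if d > best["density"] + _EPS:
                best["density"] = d
                best["labels"] = labels.copy()
            return
        u, v = edges[j]
        for c in range(min(used + 1, K)):
            labels[j] = c
            add(c, u, v)
            rec(j + 1, used + (1 if c == used else 0))
            remove(c, u, v)

    rec(0, 0)
    return best["labels"], best["density"], best["leaves"]


def _enumerate_model2(net: Network, K: int, mode: str):
    """Enumeration of all covering assignments (non-empty label sets per
    link) with label symmetry quotiented by first-use order."""
    m = net.m
    edges = net.edges
    counts = [0] * K
    node_counts = [dict() for _ in range(K)]
    assignment: list = [None] * m
    best = {"assign": None, "density": -1.0, "leaves": 0}

    def add(cs, u, v):
        for c in cs:
            counts[c] += 1
            for w in (u, v):
                node_counts[c][w] = node_counts[c].get(w, 0) + 1

    def remove(cs, u, v):
        for c in cs:
            counts[c] -= 1
            for w in (u, v):
                node_counts[c][w] -= 1
                if node_counts[c][w] == 0:
                    del node_counts[c][w]

    def rec(j: int, used: int):
        if j == m:
            best["leaves"] += 1
            d = _evaluate(counts, node_counts, mode)
            if d > best["density"] + _EPS:
                best["density"] = d
                best["assign"] = [set(s) for s in assignment]
            return
        u, v = edges[j]
        choices = []
        for size in range(used + 1):
            for subset in itertools.combinations(range(used), size):
                for t in range(K - used + 1):
                    if size + t >= 1:
                        choices.append((subset, t))
        choices.sort(key=lambda st: (len(st[0]) + st[1], st[0]))
        for subset, t in choices:
            cs = list(subset) + list(range(used, used + t))
            assignment[j] = cs
            add(cs, u, v)
            rec(j + 1, used + t)
            remove(cs, u, v)
            assignment[j] = None

    rec(0, 0)
    return best["assign"], best["density"], best["leaves"]


def _verify(net: Network, partition: LinkPartition, model: str) -> None:
    K = partition.K
    x = np.zeros((net.m, K), dtype=np.int64)
    for j, ks in partition.assignment.items():
        for k in ks:
            x[j - 1, k - 1] = 1
    B = incidence_matrix(net)
    y = ((B.T @ x) > 0).astype(np.int64)
    check = check_model1_feasible if model == "model1" else check_model2_feasible
    if not check(net, x, y):
        raise AssertionError(f"internal error: {model} solution infeasible")


def solve_model1(
    net: Network, K: int, max_links: int = 14, mode: str = "link-weighted"
) -> ModelSolution:
    """Maximize the partition density over disjoint assignments of the
    links into at most K communities.

    Tries the clique-partition search first (a hit has density exactly 1
    and is provably optimal); otherwise falls back to exhaustive
    restricted-growth enumeration, which requires ``net.m <= max_links``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    labels0 = _clique_partition_search(net, K)
    if labels0 is not None:
        partition = LinkPartition.from_labels([c + 1 for c in labels0], K)
        size = 1
    else:
        if net.m > max_links:
            raise NetworkTooLarge(
                f"optimum is below 1 and m={net.m} exceeds the enumeration "
                f"cap ({max_links}); use the genetic algorithm"
            )
        labels, _, size = _enumerate_model1(net, K, mode)
        partition = LinkPartition.from_labels([c + 1 for c in labels], K)
    density = partition_density(net, partition, mode).D
    _verify(net, partition, "model1")
    return ModelSolution(partition, density, "model1", K, size)


def solve_model2(
    net: Network, K: int, max_links: int = 10, mode: str = "link-weighted"
) -> ModelSolution:
    """Maximize the duplicated-link-weighted partition density over
    covering assignments (each link in at least one of K communities)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    cover = _clique_cover_search(net, K)
    if cover is not None:
        assignment = {j + 1: frozenset(c + 1 for c in cs) for j, cs in enumerate(cover)}
        partition = LinkPartition(assignment, K)
        size = 1
    else:
        if net.m > max_links:
            raise NetworkTooLarge(
                f"optimum is below 1 and m={net.m} exceeds the enumeration "
                f"cap ({max_links}); use the genetic algorithm"
            )
        assign, _, size = _enumerate_model2(net, K, mode)
        assignment = {j + 1: frozenset(c + 1 for c in cs) for j, cs in enumerate(assign)}
        partition = LinkPartition(assignment, K)
    density = partition_density(net, partition, mode).D
    _verify(net, partition, "model2")
    return ModelSolution(partition, density, "model2", K, size)


def select_K(
    net: Network,
    k_range,
    model: str = "model1",
    mode: str = "link-weighted",
    max_links: int | None = None,
):
    """Scan community counts and pick the best one.

    Solves the chosen model for every K in ``k_range`` and returns
    ``(K_star, results)`` where ``results`` maps K to a
    :class:`ModelSolution` (or to None when the only available certificate
    is "optimum below 1": the clique search failed and the network is too
    large to enumerate).  ``K_star`` is the smallest K attaining the
    maximum density — the density is non-decreasing in K once singleton
    communities are allowed, so "find the maximum" alone would be
    degenerate.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty K range")
    solver = solve_model1 if model == "model1" else solve_model2
    kwargs = {} if max_links is None else {"max_links": max_links}
    results = {}
    for K in ks:
        try:
            results[K] = solver(net, K, mode=mode, **kwargs)
        except NetworkTooLarge:
            results[K] = None  # optimum provably < 1, value unknown
    solved = {K: s for K, s in results.items() if s is not None}
    if not solved:
        raise NetworkTooLarge("no K in the range could be solved exactly")
    best_density = max(s.density for s in solved.values())
    if best_density < 1.0 - _EPS and any(s is None for s in results.values()):
        raise NetworkTooLarge(
            "some K could not be enumerated and the best solved density is "
            "below 1; the scan cannot be ranked exactly"
        )
    K_star = min(K for K, s in solved.items() if s.density >= best_density - _EPS)
    return K_star, results
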