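"""Link-community partition density.

For a community *c* holding ``m_c`` links whose endpoints induce ``n_c``
nodes, the community's link density is the induced-subgraph edge density

    D_c = 2 m_c / (n_c (n_c - 1)),

which is 0 for an empty community and 1 exactly when the community's links
form a complete graph on its induced nodes.  The *partition density* D of a
link partition is the average of the D_c; by default the average is
link-weighted,

    D = sum_c m_c D_c / sum_c m_c,

where under an overlapping assignment a link counts once in every community
containing it (duplicated-link convention).  A plain mean over non-empty
communities is available as ``mode="community-mean"``.

The earlier Ahn–Bagrow–Lehmann density is provided as a baseline; it
rescales each community by its tree/clique extremes and therefore assigns
0 to *every* partition of a tree, which is what motivates the new density.

Caveat: single-link communities have density 1 (m=1, n=2), so with an
unbounded number of communities D is maximized trivially by atomizing the
link set.  D is only a meaningful objective under a fixed or bounded
community count, which is how both the exact solvers and the genetic
algorithm use it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Set

from .graph import Network

__all__ = [
    "LinkPartition",
    "CommunityStats",
    "DensityReport",
    "induced_nodes",
    "community_density",
    "partition_density",
    "ahn_partition_density",
    "MODES",
]

MODES = ("link-weighted", "community-mean")


@dataclass(frozen=True)
class LinkPartition:
    """Assignment of every link to a non-empty set of community labels.

    ``assignment`` maps 1-based link indices to frozensets of labels in
    ``1..K``; a label may be unused (empty community).  Disjoint partitions
    are the special case of all-singleton sets.
    """

    assignment: Mapping[int, FrozenSet[int]]
    K: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "assignment",
            {int(j): frozenset(int(k) for k in ks) for j, ks in self.assignment.items()},
        )
        for j, ks in self.assignment.items():
            if not ks:
                raise ValueError(f"link {j} has an empty community set")
            if any(k < 1 or k > self.K for k in ks):
                raise ValueError(f"link {j} uses a label outside 1..{self.K}")

    @classmethod
    def from_labels(cls, labels: Sequence[int], K: int | None = None) -> "LinkPartition":
        """Disjoint partition from one label per link (link order 1..m)."""
        if K is None:
            K = max(labels) if len(labels) else 0
        return cls({j + 1: frozenset([lab]) for j, lab in enumerate(labels)}, K)

    @classmethod
    def from_communities(
        cls, communities: Mapping[int, Iterable[int]], m: int, K: int | None = None
    ) -> "LinkPartition":
        """Partition from a label -> link-ids mapping covering links 1..m."""
        if K is None:
            K = max(communities) if communities else 0
        assignment: Dict[int, set] = {j: set() for j in range(1, m + 1)}
        for label, links in communities.items():
            for j in links:
                if j not in assignment:
                    raise ValueError(f"community {label} references unknown link {j}")
                assignment[j].add(label)
        missing = [j for j, ks in assignment.items() if not ks]
        if missing:
            raise ValueError(f"links not covered by any community: {missing}")
        return cls({j: frozenset(ks) for j, ks in assignment.items()}, K)

    @property
    def is_disjoint(self) -> bool:
        return all(len(ks) == 1 for ks in self.assignment.values())

    def communities(self) -> Dict[int, Set[int]]:
        """Label -> set of link ids, for labels 1..K (possibly empty sets)."""
        out: Dict[int, Set[int]] = {k: set() for k in range(1, self.K + 1)}
        for j, ks in self.assignment.items():
            for k in ks:
                out[k].add(j)
        return out

    def validate_cover(self, m: int) -> None:
        """Check the partition covers exactly links 1..m."""
        links = set(self.assignment)
        expected = set(range(1, m + 1))
        if links != expected:
            raise ValueError(
                f"partition covers links {sorted(links)}, network has 1..{m}"
            )


@dataclass(frozen=True)
class CommunityStats:
    label: int
    m_c: int
    n_c: int
    D_c: float


@dataclass(frozen=True)
class DensityReport:
    """Per-community statistics plus the aggregate partition density."""

    communities: tuple
    D: float
    mode: str

    def to_tsv(self) -> str:
        lines = ["community\tm_c\tn_c\tD_c"]
        for c in self.communities:
            lines.append(f"{c.label}\t{c.m_c}\t{c.n_c}\t{c.D_c:.6f}")
        lines.append(f"D ({self.mode})\t\t\t{self.D:.6f}")
        return "\n".join(lines) + "\n"


def induced_nodes(net: Network, links: Iterable[int]) -> Set:
    """Union of the endpoints of the given 1-based link indices."""
    out: Set = set()
    for j in links:
        u, v = net.edge(j)
        out.add(u)
        out.add(v)
    return out


def community_density(m_c: int, n_c: int) -> float:
    """Induced-subgraph edge density 2 m_c / (n_c (n_c - 1)).

    0 for an empty community; 1 exactly when the community is a clique.
    """
    if m_c == 0:
        return 0.0
    if n_c < 2:
        raise ValueError(f"community with {m_c} links cannot induce {n_c} nodes")
    if m_c > n_c * (n_c - 1) // 2:
        raise ValueError(f"impossible stats: m_c={m_c} exceeds C({n_c},2)")
    return 2.0 * m_c / (n_c * (n_c - 1))


def partition_density(
    net: Network, partition: LinkPartition, mode: str = "link-weighted"
) -> DensityReport:
    """Evaluate the partition density of a (possibly overlapping) partition.

    Under overlap, a link in several communities counts once per
    membership, both in each community's m_c and in the link-weighted
    denominator.  Empty communities contribute nothing in either mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    partition.validate_cover(net.m)
    stats = []
    for label, links in sorted(partition.communities().items()):
        m_c = len(links)
        n_c = len(induced_nodes(net, links))
        stats.append(CommunityStats(label, m_c, n_c, community_density(m_c, n_c)))
    nonempty = [c for c in stats if c.m_c > 0]
    if mode == "link-weighted":
        total = sum(c.m_c for c in nonempty)
        D = sum(c.m_c * c.D_c for c in nonempty) / total
    else:
        D = sum(c.D_c for c in nonempty) / len(nonempty)
    return DensityReport(tuple(stats), D, mode)


def ahn_partition_density(net: Network, partition: LinkPartition) -> float:
    """Ahn–Bagrow–Lehmann partition density (disjoint partitions only).

    D = (2/M) sum_c m_c (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)),
    with communities of n_c <= 2 contributing 0 (the standard convention).
    Each community's term is 0 when it is a tree and maximal when it is a
    clique, so tree networks score 0 under every partition.
    """
    if not partition.is_disjoint:
        raise ValueError("the baseline density is defined for disjoint partitions")
    partition.validate_cover(net.m)
    total = 0.0
    for links in partition.communities().values():
        m_c = len(links)
        if m_c == 0:
            continue
        n_c = len(induced_nodes(net, links))
        if n_c <= 2:
            continue
        total += m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))
    return 2.0 / net.m * total
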