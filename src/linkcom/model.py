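"""Model/Results interface tying the solvers together.

:class:`LinkCommunityModel` is constructed from a network (or an edge
list) plus the community-count bound K; ``fit()`` dispatches to the
genetic algorithm or to one of the exact integer-programming solvers and
returns a :class:`LinkCommunityResults` carrying the partition, the
density report, node memberships and — for the GA — the fitness trace.
``scan_k()`` repeats the fit over a range of K and recommends the
smallest K attaining the maximum density.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import exact, ga
from .density import LinkPartition, DensityReport, partition_density
from .graph import Network, read_edge_list

__all__ = ["LinkCommunityModel", "LinkCommunityResults", "KScanResults"]


class LinkCommunityModel:
    """Link-community detection on an undirected simple graph.

    Parameters
    ----------
    network
        The graph to partition.
    n_communities
        Maximum number of communities K.  The density objective is only
        meaningful under a bound on K (single-link communities have
        density 1, so an unbounded K atomizes the links); unused
        communities stay empty, so the effective count is emergent.
    density_mode
        ``"link-weighted"`` (default) or ``"community-mean"`` averaging.
    """

    def __init__(self, network: Network, n_communities: int,
                 density_mode: str = "link-weighted"):
        if n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        self.network = network
        self.n_communities = int(n_communities)
        self.density_mode = density_mode

    @classmethod
    def from_edge_list(cls, source, n_communities: int, **kwargs) -> "LinkCommunityModel":
        """Build from a path, text stream, or multi-line string edge list."""
        return cls(read_edge_list(source), n_communities, **kwargs)

    @classmethod
    def from_networkx(cls, graph, n_communities: int, **kwargs) -> "LinkCommunityModel":
        return cls(Network.from_networkx(graph), n_communities, **kwargs)

    # ------------------------------------------------------------------

    def fit(self, method: str = "ga", seed: Optional[int] = None,
            restarts: int = 1, max_links: Optional[int] = None,
            **ga_params) -> "LinkCommunityResults":
        """Fit the link partition.

        ``method`` is ``"ga"`` (hybrid genetic/SOM optimizer), ``"model1"``
        (exact, disjoint links) or ``"model2"`` (exact, overlapping links).
        For the GA, ``restarts`` independent runs are made with seeds
        spawned from ``seed`` and the best is kept; extra keyword
        arguments become :class:`~linkcom.ga.GAConfig` fields.
        """
        if method == "ga":
            return self._fit_ga(seed=seed, restarts=restarts, **ga_params)
        if method in ("model1", "model2"):
            solver = exact.solve_model1 if method == "model1" else exact.solve_model2
            kwargs = {} if max_links is None else {"max_links": max_links}
            sol = solver(self.network, self.n_communities,
                         mode=self.density_mode, **kwargs)
            return LinkCommunityResults._from_exact(self, sol, seed)
        raise ValueError(f"unknown method {method!r}")

    def _fit_ga(self, seed=None, restarts=1, **ga_params) -> "LinkCommunityResults":
        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
        best: Optional[ga.GAResult] = None
        for s in seeds:
            config = ga.GAConfig(K=self.n_communities, seed=int(s),
                                 mode=self.density_mode, **ga_params)
            result = ga.run_ga(self.network, config)
            if best is None or result.best_fitness > best.best_fitness:
                best = result
        return LinkCommunityResults._from_ga(self, best, seed, restarts)

    def scan_k(self, k_min: int, k_max: int, method: str = "model1",
               seed: Optional[int] = None, restarts: int = 1,
               max_links: Optional[int] = None, **ga_params) -> "KScanResults":
        """Fit for every K in [k_min, k_max] and recommend the smallest K
        attaining the maximum density."""
        if k_min < 1 or k_max < k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        ks = range(k_min, k_max + 1)
        if method in ("model1", "model2"):
            k_star, sols = exact.select_K(self.network, ks, model=method,
                                          mode=self.density_mode,
                                          max_links=max_links)
            rows = []
            for K in ks:
                sol = sols[K]
                rows.append({"K": K,
                             "density": np.nan if sol is None else sol.density,
                             "note": "optimum < 1 (not enumerable)"
                             if sol is None else "exact"})
            return KScanResults(pd.DataFrame(rows), k_star, sols, method)
        if method == "ga":
            rows, sols = [], {}
            for i, K in enumerate(ks):
                sub = LinkCommunityModel(self.network, K, self.density_mode)
                res = sub.fit(method="ga", restarts=restarts, **ga_params,
                              seed=None if seed is None else seed + 1000 * i)
                sols[K] = res
                rows.append({"K": K, "density": res.density, "note": "ga"})
            table = pd.DataFrame(rows)
            best = table["density"].max()
            k_star = int(table.loc[table["density"] >= best - 1e-12, "K"].min())
            return KScanResults(table, k_star, sols, method)
        raise ValueError(f"unknown method {method!r}")


@dataclass
class KScanResults:
    """Outcome of a community-count scan."""

    table: pd.DataFrame
    recommended_k: int
    solutions: Dict[int, object]
    method: str

    def summary(self) -> str:
        lines = [f"K scan ({self.method}); recommended K = {self.recommended_k}",
                 self.table.to_string(index=False)]
        return "\n".join(lines)


class LinkCommunityResults:
    """Fitted link-community partition.

    Attributes
    ----------
    partition : LinkPartition
        Hard (disjoint) assignment — for Model-2 and the GA's overlapping
        decode see ``overlap_partition``.
    density : float
        Partition density of the primary partition.
    report : DensityReport
        Per-community (m_c, n_c, D_c) statistics.
    node_membership : pandas.DataFrame
        Nodes x communities binary membership (a node is in every
        community that contains one of its links).
    """

    def __init__(self, model: LinkCommunityModel, method: str,
                 partition: LinkPartition, report: DensityReport,
                 overlap_partition: Optional[LinkPartition] = None,
                 overlap_report: Optional[DensityReport] = None,
                 ga_result: Optional[ga.GAResult] = None,
                 exact_solution: Optional[exact.ModelSolution] = None,
                 seed=None, restarts: int = 1):
        self.model = model
        self.method = method
        self.partition = partition
        self.report = report
        self.overlap_partition = overlap_partition
        self.overlap_report = overlap_report
        self.ga_result = ga_result
        self.exact_solution = exact_solution
        self.seed = seed
        self.restarts = restarts
        self.density = report.D
        # memberships reflect the same partition the density report scores;
        # the GA's tau-overlap decode stays available via overlap_partition
        net = model.network
        member = np.zeros((net.n, partition.K), dtype=np.int64)
        for j, ks in partition.assignment.items():
            u, v = net.edge(j)
            for k in ks:
                member[net.node_index(u), k - 1] = 1
                member[net.node_index(v), k - 1] = 1
        self.node_membership = pd.DataFrame(
            member, index=list(net.nodes),
            columns=[f"c{k}" for k in range(1, partition.K + 1)])

    # -- constructors ---------------------------------------------------

    @classmethod
    def _from_ga(cls, model, result: ga.GAResult, seed, restarts):
        return cls(model, "ga", result.partition, result.report,
                   overlap_partition=result.overlap_partition,
                   overlap_report=result.overlap_report,
                   ga_result=result, seed=seed, restarts=restarts)

    @classmethod
    def _from_exact(cls, model, sol: exact.ModelSolution, seed):
        overlap = None if sol.partition.is_disjoint else sol.partition
        return cls(model, sol.model, sol.partition,
                   partition_density(model.network, sol.partition,
                                     model.density_mode),
                   overlap_partition=overlap, exact_solution=sol, seed=seed)

    # -- derived quantities ---------------------------------------------

    @property
    def n_communities_effective(self) -> int:
        return sum(1 for c in self.report.communities if c.m_c > 0)

    @property
    def overlapping_nodes(self) -> list:
        mask = self.node_membership.sum(axis=1) > 1
        return list(self.node_membership.index[mask])

    @property
    def fitness_trace(self) -> Optional[pd.DataFrame]:
        if self.ga_result is None:
            return None
        return pd.DataFrame({"epoch": np.arange(1, len(self.ga_result.trace_best) + 1),
                             "best_fitness": self.ga_result.trace_best,
                             "mean_fitness": self.ga_result.trace_mean})

    def communities(self) -> Dict[int, set]:
        return {k: links for k, links in self.partition.communities().items() if links}

    # -- presentation ---------------------------------------------------

    def summary(self) -> str:
        net = self.model.network
        head = [
            "Link Community Detection Results",
            "=" * 46,
            f"method:               {self.method}",
            f"nodes / links:        {net.n} / {net.m}",
            f"K (bound):            {self.partition.K}",
            f"effective communities:{self.n_communities_effective:>5}",
            f"density mode:         {self.report.mode}",
            f"partition density:    {self.density:.4f}",
            f"overlapping nodes:    {len(self.overlapping_nodes)}",
        ]
        if self.ga_result is not None:
            head.append(f"epochs run:           {self.ga_result.epochs_run}"
                        f" (restarts: {self.restarts})")
        rows = ["", "community   m_c   n_c     D_c", "-" * 32]
        for c in self.report.communities:
            if c.m_c > 0:
                rows.append(f"{c.label:>9}{c.m_c:>6}{c.n_c:>6}{c.D_c:>9.4f}")
        return "\n".join(head + rows)

    def links_tsv(self) -> str:
        net = self.model.network
        lines = ["link_id\tendpoint_u\tendpoint_v\tcommunity_labels"]
        for j in range(1, net.m + 1):
            u, v = net.edge(j)
            labels = ",".join(str(k) for k in sorted(self.partition.assignment[j]))
            lines.append(f"{j}\t{u}\t{v}\t{labels}")
        return "\n".join(lines) + "\n"

    def nodes_tsv(self) -> str:
        lines = ["node\tcommunity_labels\tis_overlapping"]
        for node, row in self.node_membership.iterrows():
            labels = ",".join(str(k + 1) for k in np.flatnonzero(row.values))
            lines.append(f"{node}\t{labels}\t{int(row.sum() > 1)}")
        return "\n".join(lines) + "\n"

    def save(self, outdir) -> None:
        """Write links/nodes/density TSVs, the GA trace CSV and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "links.tsv").write_text(self.links_tsv())
        (outdir / "nodes.tsv").write_text(self.nodes_tsv())
        (outdir / "density.tsv").write_text(self.report.to_tsv())
        if self.ga_result is not None:
            self.fitness_trace.to_csv(outdir / "trace.csv", index=False)
        manifest = {
            "method": self.method,
            "seed": self.seed,
            "restarts": self.restarts,
            "density_mode": self.report.mode,
            "K": self.partition.K,
            "effective_communities": self.n_communities_effective,
            "density": self.density,
            "n": self.model.network.n,
            "m": self.model.network.m,
        }
        if self.ga_result is not None:
            manifest["ga_config"] = asdict(self.ga_result.config)
        if self.exact_solution is not None:
            manifest["enumeration_size"] = self.exact_solution.enumeration_size
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def plot_trace(self, ax=None):
        """Plot the GA best/mean fitness trace (requires matplotlib)."""
        if self.ga_result is None:
            raise ValueError("no fitness trace: results are from an exact solver")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        trace = self.fitness_trace
        ax.plot(trace["epoch"], trace["best_fitness"], label="best")
        ax.plot(trace["epoch"], trace["mean_fitness"], label="mean", alpha=0.6)
        ax.set_xlabel("epoch")
        ax.set_ylabel("partition density")
        ax.legend()
        return ax
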