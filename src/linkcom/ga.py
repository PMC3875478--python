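"""Hybrid genetic / self-organizing-map optimizer for link communities.

The genotype is a chromosome matrix ``X`` (links x K) of membership
strengths, each row normalized to sum 1.  The phenotype is a binary
partition matrix ``Z``: the hard decode takes each row's argmax; the
overlapping decode keeps every community whose strength is within a
factor ``tau`` of the row maximum, so a link can join several
communities.  Fitness is the link partition density of ``Z``.

Each epoch runs: fitness evaluation -> descending sort with elitist
re-injection -> column crossover of rank-adjacent pairs -> row-copy
mutation of a fraction ``p`` of individuals -> a SOM reinforcement sweep
-> row re-normalization.  The SOM step computes, for every link, the
*community ID variance* — the fraction of its adjacent links (itself
included) sharing its community — and pushes coherent neighborhoods
together while pulling incoherent memberships down; this local smoothing
on the line graph is what lets the population escape fragmented decodes.

``K`` is an upper bound only: unused columns decode to empty communities,
which the density objective ignores, so the effective number of
communities is emergent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .density import DensityReport, LinkPartition, community_density, partition_density
from .graph import Network, incidence_matrix, link_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "GAResult",
    "init_population",
    "decode_hard",
    "decode_overlap",
    "fitness",
    "sort_with_elitism",
    "crossover",
    "mutate",
    "community_id_variance",
    "som_update",
    "normalize",
    "node_memberships",
    "partition_from_matrix",
    "run_ga",
]

_ROW_SUM_TOL = 1e-9


@dataclass
class GAConfig:
    """Parameters of the GA/SOM run.

    K is the maximum number of communities (upper bound; the effective
    count is emergent).  N individuals evolve for at most T epochs with
    mutation probability p; the SOM sweep uses variance threshold theta
    and step sizes alpha (reinforce/weaken neighbors) and beta (suppress
    non-neighbors), both decayed linearly to a floor of 1e-3.  eta is the
    crossover fraction, tau the overlapping-decode threshold.
    mutation_rule selects among the three row-mutation rules (see
    :func:`mutate`).  A run stops at epoch T, as soon as the density
    ceiling of 1 is reached (a certified optimum), or — when patience is
    set — after that many epochs without improvement; by default patience
    is off, because the late, rare improvements after long plateaus are
    exactly what escape merged-community local optima.
    """

    K: int
    N: int = 40
    T: int = 2000
    p: float = 0.3
    theta: float = 0.2
    alpha: float = 1.0
    beta: float = 0.2
    eta: float = 1.0
    tau: float = 0.8
    mutation_rule: str = "random"
    patience: Optional[int] = None
    seed: Optional[int] = None
    mode: str = "link-weighted"

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for name in ("p", "eta"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        if self.theta < 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("theta, alpha, beta must be non-negative")
        if self.mutation_rule not in MUTATION_RULES:
            raise ValueError(f"mutation_rule must be one of {MUTATION_RULES}")
        if self.patience is not None and self.patience < 1:
            raise ValueError("patience must be None or >= 1")


@dataclass
class GAResult:
    """Outcome of a GA run: the best-ever individual and its decodes."""

    config: GAConfig
    best_chromosome: np.ndarray
    best_fitness: float
    hard_matrix: np.ndarray
    overlap_matrix: np.ndarray
    partition: LinkPartition
    overlap_partition: LinkPartition
    report: DensityReport
    overlap_report: DensityReport
    node_membership: np.ndarray
    trace_best: np.ndarray
    trace_mean: np.ndarray
    epochs_run: int

    @property
    def effective_k(self) -> int:
        """Number of non-empty communities in the hard decode."""
        return int((self.hard_matrix.sum(axis=0) > 0).sum())


def init_population(m: int, K: int, N: int, rng: np.random.Generator) -> List[np.ndarray]:
    """N chromosomes with i.i.d. uniform entries, rows normalized to 1."""
    pop = []
    for _ in range(N):
        X = rng.uniform(size=(m, K))
        pop.append(X / X.sum(axis=1, keepdims=True))
    return pop


def decode_hard(X: np.ndarray) -> np.ndarray:
    """One-hot row-argmax decode; ties go to the lowest community index."""
    Z = np.zeros_like(X, dtype=np.int64)
    Z[np.arange(X.shape[0]), np.argmax(X, axis=1)] = 1
    return Z


def decode_overlap(X: np.ndarray, tau: float) -> np.ndarray:
    """Keep every community within a factor ``tau`` of the row maximum.

    Always includes the row argmax, so this is a relaxation of
    :func:`decode_hard`; at ``tau=1`` the two agree wherever row maxima
    are unique.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    rowmax = X.max(axis=1, keepdims=True)
    Z = (X >= tau * rowmax).astype(np.int64)
    Z[np.arange(X.shape[0]), np.argmax(X, axis=1)] = 1
    return Z


def fitness(Z: np.ndarray, B: np.ndarray, mode: str = "link-weighted") -> float:
    """Partition density of the binary assignment ``Z``.

    Community sizes are the column sums of Z; induced node counts are the
    positive entries of ``B.T @ z_k``.  Matches the density module's value
    on the equivalent link partition (duplicated-link convention under
    overlap).
    """
    if Z.shape[0] != B.shape[0]:
        raise ValueError("Z and B disagree on the number of links")
    m_k = Z.sum(axis=0)
    n_k = ((B.T @ Z) > 0).sum(axis=0)
    mask = m_k > 0
    d_k = np.array(
        [community_density(int(mc), int(nc)) for mc, nc in zip(m_k[mask], n_k[mask])]
    )
    if mode == "link-weighted":
        return float((m_k[mask] * d_k).sum() / m_k[mask].sum())
    if mode == "community-mean":
        return float(d_k.mean())
    raise ValueError(f"unknown mode {mode!r}")


def sort_with_elitism(
    population: List[np.ndarray],
    fitnesses: np.ndarray,
    previous_best: Optional[Tuple[np.ndarray, float]] = None,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Sort descending by fitness (stable), re-injecting the previous best
    over the current worst when the population has regressed."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    order = np.argsort(-fitnesses, kind="stable")
    population = [population[i] for i in order]
    fitnesses = fitnesses[order]
    if previous_best is not None and previous_best[1] > fitnesses[0]:
        population[-1] = previous_best[0].copy()
        fitnesses[-1] = previous_best[1]
        order = np.argsort(-fitnesses, kind="stable")
        population = [population[i] for i in order]
        fitnesses = fitnesses[order]
    return population, fitnesses


def crossover(
    Xa: np.ndarray, Xb: np.ndarray, eta: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Exchange information along one random column.

    Column k of each parent is incremented by ``eta`` times column k of
    the *other* parent's hard decode; outputs are un-normalized
    temporaries.
    """
    if Xa.shape != Xb.shape:
        raise ValueError("parents must have the same shape")
    k = int(rng.integers(Xa.shape[1]))
    Za, Zb = decode_hard(Xa), decode_hard(Xb)
    Xa2, Xb2 = Xa.copy(), Xb.copy()
    Xa2[:, k] += eta * Zb[:, k]
    Xb2[:, k] += eta * Za[:, k]
    return Xa2, Xb2


MUTATION_RULES = ("copy", "swap", "random")


def mutate(X: np.ndarray, rng: np.random.Generator, rule: str = "copy") -> np.ndarray:
    """Mutate one or two rows of a chromosome (in place).

    Three interchangeable rules operate on two distinct random rows r1,
    r2: ``"copy"`` overwrites row r1 with a copy of row r2, ``"swap"``
    exchanges the two rows, and ``"random"`` resamples row r1 uniformly
    in [0, 1].  The random rule reintroduces membership diversity that
    the SOM sweep would otherwise quench, so it is the default for full
    runs (see :class:`GAConfig`).
    """
    m = X.shape[0]
    if m < 2:
        logger.warning("mutation skipped: network has a single link")
        return X
    r1, r2 = rng.choice(m, size=2, replace=False)
    if rule == "copy":
        X[r1] = X[r2]
    elif rule == "swap":
        X[[r1, r2]] = X[[r2, r1]]
    elif rule == "random":
        X[r1] = rng.uniform(size=X.shape[1])
    else:
        raise ValueError(f"unknown mutation rule {rule!r}")
    return X


def _id_variances(Z: np.ndarray, E: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-link community ID variance v_i = a_i / g_i and the community
    index of each link, from a hard decode."""
    com = np.argmax(Z, axis=1)
    A = E > 0  # adjacency on the line graph, self included (diag of E is 2)
    same = com[:, None] == com[None, :]
    g = A.sum(axis=1)
    a = (A & same).sum(axis=1)
    return a / g, com


def community_id_variance(Z: np.ndarray, E: np.ndarray, link_id: int) -> float:
    """Fraction of the links adjacent to 1-based ``link_id`` (itself
    included) that share its community."""
    v, _ = _id_variances(Z, E)
    return float(v[link_id - 1])


def som_update(
    X: np.ndarray,
    Z: np.ndarray,
    E: np.ndarray,
    theta: float,
    alpha_t: float,
    beta_t: float,
) -> np.ndarray:
    """One SOM sweep over all links (in place on a temporary chromosome).

    For each link i in community k*: if its community ID variance is at
    least ``theta``, add ``alpha_t`` to the k*-strength of i and of every
    neighbor sharing k*, and subtract ``beta_t`` from the k*-strength of
    every non-neighbor; otherwise subtract ``alpha_t`` from i and its
    same-community neighbors.  Entries pushed negative are reset to 0.01.

    All contributions are computed from the decode ``Z`` taken at the
    start of the sweep and accumulated, so the update is order-independent.
    """
    v, _ = _id_variances(Z, E)
    A = E > 0
    com_onehot = Z.astype(float)
    reinforce = (v >= theta).astype(float)
    sign = 2.0 * reinforce - 1.0  # +1 reinforce branch, -1 weaken branch
    S = (A & (np.argmax(Z, axis=1)[:, None] == np.argmax(Z, axis=1)[None, :]))
    delta = alpha_t * (S.T.astype(float) @ (com_onehot * sign[:, None]))
    delta -= beta_t * ((~A).T.astype(float) @ (com_onehot * reinforce[:, None]))
    X += delta
    X[X < 0] = 0.01
    return X


def normalize(X: np.ndarray) -> np.ndarray:
    """Rescale each row to sum 1 (in place); zero rows reset to uniform."""
    sums = X.sum(axis=1, keepdims=True)
    zero = sums[:, 0] <= 0
    if np.any(zero):
        logger.warning("%d zero rows reset to uniform during normalization",
                       int(zero.sum()))
        X[zero] = 1.0 / X.shape[1]
        sums = X.sum(axis=1, keepdims=True)
    X /= sums
    return X


def node_memberships(Z: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Node x K binary matrix: node i is in community k iff some link
    incident to i is in k."""
    return ((B.T @ Z) > 0).astype(np.int64)


def partition_from_matrix(Z: np.ndarray) -> LinkPartition:
    """Convert a binary partition matrix to a 1-based :class:`LinkPartition`."""
    m, K = Z.shape
    assignment = {
        j + 1: frozenset(int(k) + 1 for k in np.flatnonzero(Z[j])) for j in range(m)
    }
    return LinkPartition(assignment, K)


def run_ga(net: Network, config: GAConfig) -> GAResult:
    """Run the hybrid GA/SOM loop and return the best-ever individual.

    Fully reproducible from ``(config, config.seed)``: a single seeded
    generator drives initialization, crossover columns, mutation choices
    — there is no other source of randomness.
    """
    if net.m < 1:
        raise ValueError("network has no links")
    rng = np.random.default_rng(config.seed)
    B = incidence_matrix(net)
    E = link_adjacency(B)
    m, K, N = net.m, config.K, config.N

    population = init_population(m, K, N, rng)
    best_X: Optional[np.ndarray] = None
    best_fit = -math.inf
    trace_best: List[float] = []
    trace_mean: List[float] = []
    stagnant = 0
    epochs = 0

    for t in range(config.T):
        epochs = t + 1
        fits = np.array([fitness(decode_hard(X), B, config.mode) for X in population])
        if fits.max() > best_fit + 1e-12:
            best_fit = float(fits.max())
            best_X = population[int(np.argmax(fits))].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace_best.append(best_fit)
        trace_mean.append(float(fits.mean()))
        # density is bounded by 1, so a hit is a certified optimum
        if t == config.T - 1 or best_fit >= 1.0 - 1e-12:
            break
        if config.patience is not None and stagnant >= config.patience:
            break

        population, fits = sort_with_elitism(population, fits, (best_X, best_fit))

        # pairwise crossover of rank-adjacent individuals
        temporaries: List[np.ndarray] = []
        for i in range(0, N - 1, 2):
            a, b = crossover(population[i], population[i + 1], config.eta, rng)
            temporaries.extend((a, b))
        if N % 2 == 1:
            temporaries.append(population[-1].copy())

        n_mut = math.ceil(config.p * N)
        for idx in rng.choice(N, size=n_mut, replace=False):
            mutate(temporaries[idx], rng, rule=config.mutation_rule)

        decay = max(1.0 - t / config.T, 0.0)
        alpha_t = max(config.alpha * decay, 1e-3)
        beta_t = max(config.beta * decay, 1e-3)
        for X in temporaries:
            Z = decode_hard(X)
            som_update(X, Z, E, config.theta, alpha_t, beta_t)
            normalize(X)
        population = temporaries

    assert best_X is not None
    Z_hard = decode_hard(best_X)
    Z_over = decode_overlap(best_X, config.tau)
    partition = partition_from_matrix(Z_hard)
    over_partition = partition_from_matrix(Z_over)
    return GAResult(
        config=config,
        best_chromosome=best_X,
        best_fitness=best_fit,
        hard_matrix=Z_hard,
        overlap_matrix=Z_over,
        partition=partition,
        overlap_partition=over_partition,
        report=partition_density(net, partition, config.mode),
        overlap_report=partition_density(net, over_partition, config.mode),
        node_membership=node_memberships(Z_hard, B),
        trace_best=np.array(trace_best),
        trace_mean=np.array(trace_mean),
        epochs_run=epochs,
    )
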