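# Methods

## The objective

Given an undirected simple graph with `m` links, a *link partition*
assigns each link a non-empty set of community labels out of `1..K`.
For community `c`, `m_c` counts its link memberships and `n_c` the nodes
induced by its links; its density is `D_c = 2 m_c / (n_c (n_c − 1))`, the
edge density of the community's link set over its induced node pairs.
`D_c = 0` for an empty community, `D_c = 1` iff the community's links form
a complete graph.

The partition density is an average of the `D_c`. Two averaging modes are
implemented:

* `link-weighted` (default): `D = Σ_c m_c D_c / Σ_c m_c`. Under an
  overlapping assignment a link contributes once per membership — both to
  its communities' `m_c` and to the denominator — so duplicated links are
  "regarded as several links".
* `community-mean`: the unweighted mean of `D_c` over non-empty
  communities.

Both modes are bounded in `[0, 1]`, attain 1 exactly when every non-empty
community is a clique, and ignore empty communities (avoiding 0/0 and
letting K act as an upper bound). Single-link communities score
`D_c = 1` (a K2 is a clique); consequently `D` is only a meaningful
objective under fixed or bounded K — unbounded K atomizes the link set.
This is prominent API doctrine: every solver takes K as an explicit bound.

The Ahn–Bagrow–Lehmann density is kept as a baseline
(`ahn_partition_density`): `D = (2/M) Σ_c m_c (m_c − n_c + 1) /
((n_c − 2)(n_c − 1))`, communities with `n_c ≤ 2` contributing 0. Each of
its community terms vanishes on trees, which is exactly why it cannot rank
partitions of tree-like graphs; the double-star generator plus exhaustive
enumeration demonstrates the separation (baseline: all 2-partitions tie at
0; new density: the two-star split is the unique argmax).

## Exact solvers

Model-1 (each link exactly one community) and Model-2 (at least one) are
solved exactly in two phases:

1. **Clique search.** Since `D ≤ 1` with equality iff every community is a
   complete graph, a complete backtracking search over clique-structured
   assignments decides the `D = 1` case. For Model-1 this searches
   partitions of the links into ≤ K complete subgraphs; membership is
   pruned by edge compatibility (all induced node pairs must be graph
   edges whose links are, or can still be, assigned to the community).
   For Model-2 it searches clique *covers*: whenever both endpoints of a
   link already lie in a community, membership of that link is forced
   (otherwise the community could never become complete), which is what
   puts shared edges and shared triangles into both adjacent communities.
   A hit is returned as a certified optimum. This phase is fast on all
   clique-union benchmarks regardless of link count.
2. **Symmetry-reduced enumeration.** When no density-1 assignment exists,
   all assignments are enumerated with community labels in first-use
   (restricted-growth) order, with incremental `(m_c, n_c)` bookkeeping.
   This is exponential and capped (`max_links`, default 14 for Model-1 and
   10 for Model-2); beyond the cap the solver raises and points to the GA.

Tie-breaks are deterministic: first solution in canonical order (links in
index order, labels by first use, fewest memberships first in Model-2).
Every solution is re-verified against the model constraints
(`check_model1_feasible` / `check_model2_feasible`) before being returned.

`select_K` scans a K range and recommends the **smallest** K attaining the
maximum density. Smallest, because the density is non-decreasing in K once
singleton communities are possible, so "the maximum" alone is degenerate.
When the clique phase fails and the network is too large to enumerate, the
scan records "optimum < 1" for that K without a value; this is still
enough to rank K exactly whenever some K attains 1 (e.g. the five-clique
union: K = 1..4 are provably below 1, K = 5 attains 1, so K* = 5).

## The GA/SOM optimizer

Genotype: a chromosome `X` (`m × K`) of membership strengths, each row
normalized to sum 1. Phenotype: the binary partition matrix `Z` — hard
decode `z_jk = 1` iff `x_jk` is the row maximum (ties to the lowest
index), overlapping decode `z_jk = 1` iff `x_jk ≥ τ · rowmax` (always
containing the argmax, so it relaxes the hard decode). Fitness is the
partition density of the hard decode, computed from `Z` and the incidence
matrix `B`: `m_k` is the column sum, `n_k` the number of positive entries
of `Bᵀ z_k`; tested to agree exactly with the density module on the
equivalent partition.

One epoch: evaluate fitness → sort descending (stable; if the population
regressed below the best-ever individual, that individual replaces the
current worst) → cross over rank-adjacent pairs (one uniformly chosen
column k; each parent's column k is incremented by `η` times the *other*
parent's decoded column k) → mutate `⌈pN⌉` individuals (one row) → SOM
sweep on every individual → renormalize rows. The run stops at epoch `T`,
immediately when the density ceiling 1 is reached (a certified optimum),
or optionally after `patience` stagnant epochs.

The SOM sweep computes, per link `i` with community `k*`, the *community
ID variance* `v_i = a_i / g_i`: of the `g_i` links adjacent to `i` on the
line graph (including `i` itself), `a_i` share community `k*`. If
`v_i ≥ θ` the `k*`-strength of `i` and of its same-community neighbors is
increased by `α_t` and that of all non-neighbors decreased by `β_t`;
otherwise the `k*`-strength of `i` and its same-community neighbors is
decreased by `α_t`. Entries pushed negative are reset to 0.01. All
contributions are computed from the decode fixed at the start of the sweep
and summed, so the update is order-independent and vectorizes as two
matrix products. `α_t` and `β_t` decay linearly, `α_t = max(α(1 − t/T),
10⁻³)`.

### Parameters and defaults

| name | default | meaning |
|------|---------|---------|
| K | required | community-count upper bound (effective count emergent) |
| N | 40 | population size |
| T | 2000 | maximum epochs |
| p | 0.3 | fraction of individuals mutated per epoch |
| θ | 0.2 | ID-variance threshold separating reinforce/weaken branches |
| α | 1.0 | SOM neighbor step (decayed) |
| β | 0.2 | SOM non-neighbor suppression step (decayed) |
| η | 1.0 | crossover fraction |
| τ | 0.8 | overlapping-decode threshold |
| mutation_rule | `random` | one of `copy` / `swap` / `random` |
| patience | off | optional stagnation stop |

N, T, p, θ, α, β follow the benchmark settings used throughout the test
suite. Three defaults were design decisions settled empirically on the
ring/tree clique benchmarks (10 seeds each):

* **η = 1.0.** Rows are normalized, so the incumbent row maximum never
  exceeds 1; adding only `0.5 · Z` from the partner can never flip a
  decode, which makes crossover inert and leaves merged-clique local
  optima inescapable (0/10 recovery). At `η = 1.0` a transplanted
  community column dominates its rows and the decode flips.
* **`mutation_rule = "random"`.** The three row-mutation rules are
  nominally interchangeable, but copy/swap only recombine strengths the
  SOM has already collapsed to near-one-hot rows; resampling a row
  uniformly reintroduces the diversity the sweep quenches (recovery rose
  from 3–4/10 to 10/10). The `copy` rule remains the plain
  `mutate()` default and all three are selectable.
* **patience off by default.** Escapes from merged-community optima occur
  after plateaus of several hundred epochs (some ring runs improve last at
  epoch ~1200 of 2000); any small patience cuts these runs short. The
  ceiling stop (`D = 1`) makes easy instances cheap regardless.

K itself is the one parameter a user must think about: for exploratory
use, run `scan_k` (exact where feasible, GA otherwise) and take the
recommended smallest-maximizer.

For Zachary's karate club (34 nodes, 78 links) the package's reference
setting is `K = 3` with the defaults above and ≥ 10 restarts: best-of-10
fitness lands at 0.33–0.35 across seed sets with node 1 — the instructor —
assigned to all three communities through its incident links. Larger K
monotonically raises the achievable density (≈ 0.41 at K = 4, ≈ 0.48 at
K = 5) by fragmenting the periphery, which is the documented atomization
pressure, not a better community structure.

## Synthetic benchmarks

The generator module emulates the validation families used by the tests:
unions of cliques overlapping at single nodes (the five-clique benchmark:
cliques on {1–5}, {7–11}, {12–15}, {16–18}, {1,7,12,16}; 17 nodes, 35
links), two cliques sharing an edge or a triangle (the Model-2 overlap
cases), rings and trees of heterogeneous cliques joined at single nodes,
rings of cliques overlapping in small shared cliques, and the double star.
Every generator is deterministic, returns the planted partition and
overlapping node set, and records the planted density (recomputed through
the density module, not asserted by fiat). `karate_club()` exposes the
canonical Zachary graph (via networkx) relabelled 1..34.

What these families do *not* emulate: noisy inter-community links,
degree heterogeneity beyond clique sizes, or LFR-style planted noise.
Passing the clique benchmarks shows the optimizer recovers unambiguous
modular structure and certified optima; it does not certify behavior on
noisy real-world graphs, where the karate-club check is the only
real-data anchor in the suite.

## Numerical conventions

* Links and community labels are 1-based in every external artifact
  (reports, TSVs, `LinkPartition`); matrices are 0-based internally.
* Strict-improvement comparisons use an absolute epsilon of 1e-12; row
  normalization is enforced to 1e-9.
* Weighted link adjacency is `W = B Δ Bᵀ` with `Δ = diag(1/deg)`: the
  off-diagonal entry for links sharing node v is `1/deg(v)`, the random-
  walk transition weight across the common node. The per-endpoint
  alternative `1/(deg(v) − 1)` was considered and rejected because the
  package's convention matches the walker description exactly. `W` is
  computed and exposed but not used by the SOM, which operates on the
  unweighted link adjacency `E`.
* Degenerate inputs: empty edge lists, self-loops and isolated nodes are
  rejected at ingestion; duplicate edges collapse with a warning; a
  single-link network makes mutation a warned no-op; zero rows arising
  during normalization reset to uniform.

## Known limitations

* The exact solvers certify optimality only when a density-1 assignment
  exists or the network is within the enumeration cap; in between they
  refuse rather than approximate.
* The GA's overlapping decode (τ) is a post-hoc relaxation of the hard
  decode; fitness during evolution is always computed from the hard
  decode, so overlapping *links* are only found where the strength matrix
  retains near-ties. Exact Model-2 is the reliable route to overlapping
  links on small networks.
* Directed, bipartite, weighted and multigraph inputs are out of scope;
  edge-list weights are ignored with a warning.
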