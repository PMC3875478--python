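"""The GA/SOM operators and the full optimizer loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linkcom import GAConfig, Network, incidence_matrix, link_adjacency, run_ga
from linkcom.density import LinkPartition, partition_density
from linkcom.ga import (
    community_id_variance,
    crossover,
    decode_hard,
    decode_overlap,
    fitness,
    init_population,
    mutate,
    node_memberships,
    normalize,
    partition_from_matrix,
    som_update,
    sort_with_elitism,
)
from linkcom import synthetic as syn


chromosomes = st.integers(0, 10_000).map(
    lambda seed: np.random.default_rng(seed).dirichlet(
        np.ones(int(np.random.default_rng(seed + 1).integers(1, 6))),
        size=int(np.random.default_rng(seed + 2).integers(1, 12)),
    )
)


class TestInitAndDecode:
    def test_init_rows_normalized_and_deterministic(self):
        pop1 = init_population(5, 2, 4, np.random.default_rng(42))
        pop2 = init_population(5, 2, 4, np.random.default_rng(42))
        assert len(pop1) == 4
        for X, Y in zip(pop1, pop2):
            assert X.shape == (5, 2)
            assert np.allclose(X.sum(axis=1), 1.0)
            assert np.array_equal(X, Y)

    def test_init_k1_all_ones(self):
        (X,) = init_population(4, 1, 1, np.random.default_rng(0))
        assert np.allclose(X, 1.0)

    @pytest.mark.parametrize(
        "row, expected",
        [((0.2, 0.8), (0, 1)), ((0.5, 0.5), (1, 0)), ((1.0,), (1,))],
    )
    def test_decode_hard(self, row, expected):
        assert tuple(decode_hard(np.array([row]))[0]) == expected

    @pytest.mark.parametrize(
        "row, tau, expected",
        [
            ((0.45, 0.45, 0.10), 0.8, (1, 1, 0)),
            ((0.9, 0.1), 0.8, (1, 0)),
            ((0.3, 0.7), 1.0, (0, 1)),
        ],
    )
    def test_decode_overlap(self, row, tau, expected):
        assert tuple(decode_overlap(np.array([row]), tau)[0]) == expected

    def test_decode_overlap_bad_tau(self):
        with pytest.raises(ValueError):
            decode_overlap(np.ones((1, 2)), 0.0)

    @settings(max_examples=30, deadline=None)
    @given(chromosomes)
    def test_overlap_tau1_matches_hard_on_unique_maxima(self, X):
        unique = np.sum(X == X.max(axis=1, keepdims=True), axis=1) == 1
        Zo, Zh = decode_overlap(X, 1.0), decode_hard(X)
        assert np.array_equal(Zo[unique], Zh[unique])
        assert (Zo.sum(axis=1) >= 1).all()


class TestFitness:
    def test_triangle_one_community(self, triangle):
        B = incidence_matrix(triangle)
        assert fitness(np.ones((3, 1), dtype=int), B) == pytest.approx(1.0)

    def test_five_clique_ground_truth(self, five_cliques):
        net = five_cliques.network
        Z = np.zeros((net.m, 5), dtype=int)
        for j, ks in five_cliques.partition.assignment.items():
            for k in ks:
                Z[j - 1, k - 1] = 1
        assert fitness(Z, incidence_matrix(net)) == pytest.approx(1.0)

    def test_agrees_with_density_module_on_random_assignments(self, karate):
        """fitness(Z) must equal the density of the equivalent partition,
        for hard and overlapping assignments, in both modes."""
        B = incidence_matrix(karate)
        rng = np.random.default_rng(3)
        for _ in range(20):
            Z = (rng.uniform(size=(karate.m, 4)) < 0.3).astype(int)
            Z[Z.sum(axis=1) == 0, rng.integers(4)] = 1
            part = partition_from_matrix(Z)
            for mode in ("link-weighted", "community-mean"):
                assert fitness(Z, B, mode) == pytest.approx(
                    partition_density(karate, part, mode).D
                )


class TestOperators:
    def test_sort_descending_stable(self):
        pop = [np.full((1, 1), v) for v in (0.3, 0.9, 0.5)]
        spop, sfits = sort_with_elitism(pop, np.array([0.3, 0.9, 0.5]))
        assert list(sfits) == [0.9, 0.5, 0.3]
        assert spop[0][0, 0] == 0.9

    def test_previous_best_reinjected(self):
        pop = [np.full((1, 1), v) for v in (0.9, 0.2)]
        prev = (np.full((1, 1), 0.95), 0.95)
        spop, sfits = sort_with_elitism(pop, np.array([0.9, 0.2]), prev)
        assert sfits[0] == 0.95 and spop[0][0, 0] == 0.95

    def test_crossover_eta_zero_is_identity(self):
        rng = np.random.default_rng(0)
        Xa = np.array([[0.2, 0.8], [0.6, 0.4]])
        Xb = np.array([[0.9, 0.1], [0.1, 0.9]])
        a, b = crossover(Xa, Xb, 0.0, rng)
        assert np.array_equal(a, Xa) and np.array_equal(b, Xb)

    def test_crossover_adds_partner_decode_column(self):
        rng = np.random.default_rng(1)
        Xa = np.array([[0.2, 0.8], [0.6, 0.4]])
        Xb = np.array([[0.9, 0.1], [0.1, 0.9]])
        a, _ = crossover(Xa, Xb, 0.5, rng)
        changed = np.flatnonzero((a != Xa).any(axis=0))
        assert changed.size == 1
        k = int(changed[0])
        assert np.allclose(a[:, k], Xa[:, k] + 0.5 * decode_hard(Xb)[:, k])

    def test_crossover_shape_mismatch(self):
        with pytest.raises(ValueError):
            crossover(np.ones((2, 2)), np.ones((3, 2)), 0.5,
                      np.random.default_rng(0))

    def test_mutate_rules(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = mutate(X.copy(), np.random.default_rng(5), rule="copy")
        assert np.array_equal(out[0], out[1])
        sw = mutate(X.copy(), np.random.default_rng(5), rule="swap")
        assert np.array_equal(np.sort(sw, axis=0), np.sort(X, axis=0))
        rnd1 = mutate(X.copy(), np.random.default_rng(5), rule="random")
        rnd2 = mutate(X.copy(), np.random.default_rng(5), rule="random")
        assert np.array_equal(rnd1, rnd2)  # seeded reproducibility

    def test_mutate_single_link_noop(self, caplog):
        X = np.array([[0.5, 0.5]])
        with caplog.at_level("WARNING"):
            out = mutate(X.copy(), np.random.default_rng(0))
        assert np.array_equal(out, X)

    def test_normalize(self):
        X = np.array([[2.0, 2.0], [0.01, 0.03]])
        normalize(X)
        assert np.allclose(X, [[0.5, 0.5], [0.25, 0.75]])

    def test_normalize_zero_row_reset(self, caplog):
        X = np.array([[0.0, 0.0], [1.0, 3.0]])
        with caplog.at_level("WARNING"):
            normalize(X)
        assert np.allclose(X[0], 0.5)


class TestSOM:
    def test_variance_isolated_pair(self):
        net = Network.from_edges([(1, 2)])
        E = link_adjacency(incidence_matrix(net))
        assert community_id_variance(np.array([[1]]), E, 1) == 1.0

    def test_variance_triangle_same_community(self, triangle):
        E = link_adjacency(incidence_matrix(triangle))
        Z = np.ones((3, 1), dtype=int)
        for j in (1, 2, 3):
            assert community_id_variance(Z, E, j) == 1.0

    def test_variance_middle_link_alone(self, path3):
        # middle link of a 3-link path in its own community: a=1 of g=3
        E = link_adjacency(incidence_matrix(path3))
        Z = np.array([[1, 0], [0, 1], [1, 0]])
        assert community_id_variance(Z, E, 2) == pytest.approx(1 / 3)

    def test_zero_steps_are_identity(self, path3):
        E = link_adjacency(incidence_matrix(path3))
        X = np.array([[0.6, 0.4], [0.3, 0.7], [0.8, 0.2]])
        out = som_update(X.copy(), decode_hard(X), E, 0.5, 0.0, 0.0)
        assert np.allclose(out, X)

    def test_reinforcement_and_suppression(self, path3):
        """theta=0 puts every link on the reinforcement branch: own-community
        strengths grow for neighbors, shrink for non-neighbors."""
        E = link_adjacency(incidence_matrix(path3))
        X = np.array([[0.6, 0.4], [0.6, 0.4], [0.4, 0.6]])
        Z = decode_hard(X)
        out = som_update(X.copy(), Z, E, 0.0, 0.1, 0.05)
        # links 1,2 share community 1 and are adjacent: +0.1 each from both
        assert out[0, 0] == pytest.approx(0.6 + 0.2 - 0.0)
        # link 3 (community 2) is not adjacent to link 1: link 1 suppressed
        assert out[2, 0] < 0.4

    def test_negative_entries_become_floor(self):
        net = Network.from_edges([(1, 2), (3, 4)])  # two non-adjacent links
        E = link_adjacency(incidence_matrix(net))
        X = np.array([[0.9, 0.1], [0.05, 0.95]])
        Z = decode_hard(X)
        out = som_update(X.copy(), Z, E, 0.0, 0.1, 0.5)
        # link 2's column-1 entry driven negative by link 1's suppression
        assert out[1, 0] == pytest.approx(0.01)


class TestNodeMemberships:
    def test_five_clique_overlaps(self, five_cliques):
        net = five_cliques.network
        B = incidence_matrix(net)
        Z = np.zeros((net.m, 5), dtype=int)
        for j, ks in five_cliques.partition.assignment.items():
            Z[j - 1, next(iter(ks)) - 1] = 1
        member = node_memberships(Z, B)
        overlapping = {net.nodes[i] for i in np.flatnonzero(member.sum(axis=1) > 1)}
        assert overlapping == {1, 7, 12, 16}

    def test_single_community(self, triangle):
        member = node_memberships(np.ones((3, 1), dtype=int),
                                  incidence_matrix(triangle))
        assert member.sum() == 3


class TestRunGA:
    def test_k1_fitness_is_global_density(self, triangle):
        res = run_ga(triangle, GAConfig(K=1, N=4, T=2, seed=0))
        assert res.best_fitness == pytest.approx(1.0)

    def test_reproducible_from_seed(self):
        planted = syn.double_star(3, 3)
        r1 = run_ga(planted.network, GAConfig(K=2, N=8, T=40, seed=11))
        r2 = run_ga(planted.network, GAConfig(K=2, N=8, T=40, seed=11))
        assert np.array_equal(r1.best_chromosome, r2.best_chromosome)
        assert r1.best_fitness == r2.best_fitness
        assert np.array_equal(r1.trace_best, r2.trace_best)

    def test_trace_monotone_and_rows_normalized(self):
        planted = syn.ring_of_cliques([3, 3, 3])
        res = run_ga(planted.network, GAConfig(K=4, N=10, T=60, seed=2))
        assert (np.diff(res.trace_best) >= -1e-15).all()
        assert np.allclose(res.best_chromosome.sum(axis=1), 1.0, atol=1e-9)

    def test_report_matches_fitness(self):
        planted = syn.double_star(3, 3)
        res = run_ga(planted.network, GAConfig(K=2, N=10, T=80, seed=3))
        assert res.report.D == pytest.approx(res.best_fitness)

    @pytest.mark.parametrize(
        "make_net, K, optimum",
        [
            (lambda: syn.double_star(3, 3).network, 2, 0.5),
            (lambda: Network.from_edges(
                [(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)]), 3, 1.0),
        ],
    )
    def test_never_beats_exact_optimum(self, make_net, K, optimum):
        from linkcom import solve_model1

        net = make_net()
        exact = solve_model1(net, K).density
        assert exact == pytest.approx(optimum)
        hits = 0
        for seed in range(10):
            res = run_ga(net, GAConfig(K=K, N=20, T=250, seed=seed))
            assert res.best_fitness <= exact + 1e-12
            hits += abs(res.best_fitness - exact) < 1e-9
        assert hits >= 8

    def test_overlap_decode_recovers_shared_edge(self):
        """On two cliques sharing an edge the overlapping decode of a
        converged run can place the shared link in both communities."""
        planted = syn.two_cliques_shared_edge(4, 4)
        res = run_ga(planted.network, GAConfig(K=2, N=20, T=400, seed=1))
        assert res.best_fitness > 0.85  # hard decode cannot reach 1 here
        assert res.effective_k == 2
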