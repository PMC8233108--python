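"""Modularity, Louvain, z-Rand and consensus clustering.

networkx serves as the independent cross-check for the quality function and
for Louvain solution quality; tiny graphs are checked against exhaustive
enumeration of all set partitions.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myeloconn import (
    Partition,
    consensus_partition,
    default_gamma_grid,
    gamma_sweep,
    louvain_once,
    modularity_score,
    rand_coefficient,
    select_gamma,
    zrand,
)
from myeloconn.modularity import SweepResult, _contingency


def all_partitions(n):
    """Every set partition of n items as restricted-growth label strings."""
    def rec(i, maxlab, cur):
        if i == n:
            yield tuple(cur)
            return
        for lab in range(maxlab + 1):
            cur.append(lab + 1)
            yield from rec(i + 1, max(maxlab, lab + 1), cur)
            cur.pop()
    yield from rec(0, 0, [])


def exhaustive_max_q(A, gamma=1.0):
    return max(modularity_score(A, p, gamma) for p in all_partitions(len(A)))


class TestModularityScore:
    def test_single_community_is_zero(self, two_triangles, rng):
        assert abs(modularity_score(two_triangles, [1] * 6, 1.0)) < 1e-12
        w = np.triu(rng.random((7, 7)), 1)
        w = w + w.T
        assert abs(modularity_score(w, [1] * 7, 1.0)) < 1e-12

    def test_two_triangles_closed_form(self, two_triangles):
        q = modularity_score(two_triangles, [1, 1, 1, 2, 2, 2], 1.0)
        assert q == pytest.approx(0.5, abs=1e-15)

    def test_affine_strictly_decreasing_in_gamma(self, two_triangles):
        part = [1, 1, 1, 2, 2, 2]
        qs = [modularity_score(two_triangles, part, g) for g in (0.5, 1.25, 2.0)]
        assert qs[0] > qs[1] > qs[2]
        # affine in gamma: the mid-grid value is the mean of the endpoints
        assert qs[1] == pytest.approx((qs[0] + qs[2]) / 2)

    def test_matches_networkx_at_gamma_one(self, rng):
        w = np.triu((rng.random((9, 9)) < 0.5) * rng.random((9, 9)), 1)
        w = w + w.T
        if w.sum() == 0:
            w[0, 1] = w[1, 0] = 1.0
        g = nx.from_numpy_array(w)
        comms = [{0, 1, 2}, {3, 4, 5}, {6, 7, 8}]
        labels = np.empty(9, int)
        for lab, c in enumerate(comms, 1):
            labels[list(c)] = lab
        assert modularity_score(w, labels, 1.0) == pytest.approx(
            nx.community.modularity(g, comms, weight="weight"), abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity_score(np.zeros((3, 3)), [1, 1, 1], 1.0)


class TestLouvain:
    def test_two_cliques_recovered_at_optimum(self, two_cliques):
        p = louvain_once(two_cliques, gamma=1.0, seed=0)
        assert p.n_modules == 2
        assert len(set(p.assignment[:5])) == 1
        assert set(p.assignment[:5]) != set(p.assignment[5:])
        # closed form: two disconnected equal communities give Q = 1/2
        assert p.q == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        K = 1.0 - np.eye(8)
        p = louvain_once(K, gamma=1.0, seed=5)
        assert p.n_modules == 1 and p.q == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_given_seed(self, two_cliques, rng):
        w = np.triu(rng.random((12, 12)), 1)
        w = w + w.T
        a = louvain_once(w, gamma=1.3, seed=42)
        b = louvain_once(w, gamma=1.3, seed=42)
        assert np.array_equal(a.assignment, b.assignment) and a.q == b.q

    def test_never_below_trivial_partitions(self, rng):
        for _ in range(10):
            n = rng.integers(5, 10)
            w = np.triu((rng.random((n, n)) < 0.6) * rng.random((n, n)), 1)
            w = w + w.T
            if w.sum() == 0:
                continue
            p = louvain_once(w, gamma=1.0, seed=int(rng.integers(2 ** 31)))
            q_single = modularity_score(w, [1] * n, 1.0)
            q_singletons = modularity_score(w, np.arange(1, n + 1), 1.0)
            assert p.q >= max(q_single, q_singletons) - 1e-12

    def test_matches_exhaustive_optimum_on_small_graphs(self, rng):
        hits, total = 0, 20
        for _ in range(total):
            n = int(rng.integers(4, 8))
            w = np.triu((rng.random((n, n)) < 0.6) * rng.random((n, n)), 1)
            w = w + w.T
            if w.sum() == 0:
                w[0, 1] = w[1, 0] = 1.0
            best = exhaustive_max_q(w)
            found = max(louvain_once(w, 1.0, seed=int(s)).q
                        for s in rng.integers(0, 2 ** 31, 40))
            hits += (best - found) < 1e-12
        assert hits >= 0.9 * total

    def test_quality_competitive_with_networkx_louvain(self, rng):
        w = np.triu((rng.random((25, 25)) < 0.3) * rng.random((25, 25)), 1)
        w = w + w.T
        ours = max(louvain_once(w, 1.0, seed=int(s)).q
                   for s in rng.integers(0, 2 ** 31, 60))
        g = nx.from_numpy_array(w)
        best_nx = -np.inf
        for s in range(20):
            comms = nx.community.louvain_communities(g, weight="weight", seed=s)
            best_nx = max(best_nx, nx.community.modularity(g, comms,
                                                           weight="weight"))
        # both greedy heuristics should land on optima of comparable quality
        assert ours >= best_nx - 5e-3


class TestZRand:
    def test_rand_coefficient_pair_counting(self):
        # {A,B|C,D} vs {A,C|B,D}: 2 of 6 pairs concordant
        assert rand_coefficient([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(1 / 3)

    def test_self_similarity_positive(self):
        p = np.repeat([1, 2, 3], 5)
        assert zrand(p, p) > 0

    def test_exactly_symmetric(self, rng):
        for _ in range(20):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 4, 30)
            assert zrand(a, b) == zrand(b, a)

    def test_null_mean_near_zero(self, rng):
        vals = [zrand(rng.integers(1, 5, 60), rng.integers(1, 5, 60))
                for _ in range(1000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se + 0.02

    def test_variance_formula_matches_permutation_null(self, rng):
        """The hypergeometric mean/SD of the co-pair count agree with an
        empirical permutation null."""
        a = np.repeat([1, 2, 3, 4], 15)
        b = np.repeat([1, 2, 3, 4, 5], 12)
        ws = []
        for _ in range(2000):
            nij = _contingency(a, rng.permutation(b))
            ws.append((nij * (nij - 1) / 2).sum())
        # recompute analytic moments from the z-score definition:
        # z = (w - mu) / sigma  =>  mu = w - z * sigma for any observed w
        nij = _contingency(a, b)
        w_obs = (nij * (nij - 1) / 2).sum()
        n = 60
        M = n * (n - 1) / 2
        comb = lambda x: (x * (x - 1) / 2).sum()
        mu = comb(nij.sum(1)) * comb(nij.sum(0)) / M
        sigma = (w_obs - mu) / zrand(a, b)
        assert np.mean(ws) == pytest.approx(mu, rel=0.02)
        assert np.std(ws, ddof=1) == pytest.approx(sigma, rel=0.10)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            zrand([1, 2], [1, 2])


class TestSweep:
    def test_default_grid_has_26_levels(self):
        grid = default_gamma_grid()
        assert len(grid) == 26
        assert grid[0] == 0.5 and grid[-1] == 3.0
        assert np.allclose(np.diff(grid), 0.1)

    def test_two_cliques_stable_across_grid(self, two_cliques):
        sw = gamma_sweep(two_cliques, gammas=[0.6, 1.0, 1.4], n_runs=12, seed=1)
        # unique optimum at every gamma: stability maximal and constant
        assert np.allclose(sw.stability, sw.stability[0])
        assert sw.selected_gamma == 0.6  # tie broken toward smaller gamma
        assert sw.consensus.n_modules == 2

    def test_selection_rules(self):
        sw = SweepResult(gammas=np.array([0.5, 1.0, 1.5]), partitions=[[]] * 3,
                         mean_q=np.array([0.9, 0.5, 0.2]),
                         stability=np.array([1.0, 5.0, 5.0]))
        assert select_gamma(sw) == 1.0              # unique-ish max, smaller tie
        assert select_gamma(sw, selection="max_q") == 0.5
        with pytest.raises(ValueError):
            select_gamma(sw, selection="median")

    def test_run_seeds_derived_and_deterministic(self, two_cliques):
        a = gamma_sweep(two_cliques, gammas=[1.0], n_runs=8, seed=3)
        b = gamma_sweep(two_cliques, gammas=[1.0], n_runs=8, seed=3)
        assert np.array_equal(a.consensus.assignment, b.consensus.assignment)
        assert np.array_equal(a.mean_q, b.mean_q)

    def test_too_few_runs_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            gamma_sweep(two_cliques, gammas=[1.0], n_runs=1)


class TestConsensusPartition:
    def test_identical_inputs_returned(self):
        p = np.repeat([1, 2, 3], 4)
        out = consensus_partition([p] * 10, seed=0)
        assert rand_coefficient(out.assignment, p) == 1.0

    def test_label_permutations_equivalent(self, rng):
        p = np.repeat([1, 2, 3], 4)
        perms = []
        for _ in range(10):
            relabel = rng.permutation([1, 2, 3])
            perms.append(relabel[p - 1])
        out = consensus_partition(perms, seed=1)
        assert rand_coefficient(out.assignment, p) == 1.0

    def test_majority_dominates_random_noise(self, rng):
        p = np.repeat([1, 2, 3, 4], 15)
        inputs = [p] * 900 + [rng.integers(1, 5, 60) for _ in range(100)]
        out = consensus_partition(inputs, seed=2)
        assert rand_coefficient(out.assignment, p) == 1.0

    def test_needs_at_least_two_partitions(self):
        with pytest.raises(ValueError):
            consensus_partition([np.array([1, 1, 2, 2])], seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_nested_planted_structure_module_count_grows_with_gamma(seed):
    """Four tight cliques grouped into two loose super-groups: small gamma
    finds the two super-groups, large gamma the four cliques."""
    rng = np.random.default_rng(seed)
    n = 16
    w = np.full((n, n), 0.05)
    for g in range(2):
        w[g * 8:(g + 1) * 8, g * 8:(g + 1) * 8] = 0.4
    for c in range(4):
        w[c * 4:(c + 1) * 4, c * 4:(c + 1) * 4] = 1.0
    np.fill_diagonal(w, 0)
    lo = louvain_once(w, gamma=0.5, seed=seed)
    hi = louvain_once(w, gamma=2.0, seed=seed)
    assert lo.n_modules <= hi.n_modules
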