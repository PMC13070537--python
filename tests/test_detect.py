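import itertools

import numpy as np
import pytest

from hlca.detect import (CoreCluster, attach, build_weighted_network,
                         cluster_density, enumerate_cliques, filter_cores,
                         grow_core, hyperedge_density, hyperedge_overlap,
                         run_hlca, select_seed_cores)
from hlca.ppi_io import PPINetwork

from conftest import random_ppi


def uniform_weighted(ppi: PPINetwork):
    """Weighted view with every edge weight 1 (identical embeddings)."""
    fd = np.ones((ppi.n_nodes, 4))
    return build_weighted_network(ppi, fd)


def brute_force_maximal_cliques(ppi: PPINetwork, min_size: int = 3):
    """Exponential subset enumeration (small n only)."""
    nodes = list(ppi.node_ids)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(ppi.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    return {c for c in cliques
            if not any(c < d for d in cliques)}


class TestWeightedNetwork:
    def test_identical_rows_weight_one(self, triangle):
        gw = uniform_weighted(triangle)
        assert all(w == pytest.approx(1.0) for w in gw.weights.values())

    def test_orthogonal_rows_weight_zero(self):
        ppi = PPINetwork.from_edges([("a", "b")])
        fd = np.array([[1.0, 0.0], [0.0, 1.0]])
        gw = build_weighted_network(ppi, fd)
        assert gw.weight("a", "b") == 0.0

    def test_matches_cosine_formula(self):
        rng = np.random.default_rng(3)
        ppi = random_ppi(10, 0.4, 3)
        fd = rng.normal(size=(ppi.n_nodes, 6))
        gw = build_weighted_network(ppi, fd)
        idx = ppi.index
        for (u, v), w in gw.weights.items():
            vi, vj = fd[idx[u]], fd[idx[v]]
            expected = vi @ vj / (np.linalg.norm(vi) * np.linalg.norm(vj))
            assert w == pytest.approx(expected)
            assert -1.0 <= w <= 1.0

    def test_zero_norm_rows_get_weight_zero(self):
        ppi = PPINetwork.from_edges([("a", "b")])
        fd = np.array([[0.0, 0.0], [1.0, 1.0]])
        gw = build_weighted_network(ppi, fd)
        assert gw.weight("a", "b") == 0.0


class TestCliqueEnumeration:
    def test_triangle(self, triangle):
        cliques = enumerate_cliques(uniform_weighted(triangle))
        assert [c.members for c in cliques] == [frozenset("abc")]

    def test_k4_triangles_not_maximal(self):
        edges = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        ppi = PPINetwork.from_edges(edges)
        cliques = enumerate_cliques(uniform_weighted(ppi))
        assert [c.members for c in cliques] == [frozenset("abcd")]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        ppi = random_ppi(12, 0.4, seed)
        got = {c.members for c in enumerate_cliques(uniform_weighted(ppi))}
        assert got == brute_force_maximal_cliques(ppi)

    def test_deterministic_order(self, ci_fixture):
        ppi, _ = ci_fixture
        gw = uniform_weighted(ppi)
        assert enumerate_cliques(gw) == enumerate_cliques(gw)


class TestSeedSelection:
    def test_disjoint_triangles_both_seeds(self):
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("x", "y"), ("y", "z"), ("x", "z")])
        gw = uniform_weighted(ppi)
        seeds = select_seed_cores(enumerate_cliques(gw), gw)
        assert {s.members for s in seeds} == {frozenset("abc"), frozenset("xyz")}

    def test_shared_node_discards_stripped_remnant(self):
        # two triangles sharing c, equal weights: the tie-broken first keeps
        # its 3 members; the other falls to 2 and is dropped
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("c", "d"), ("c", "e"), ("d", "e")])
        gw = uniform_weighted(ppi)
        seeds = select_seed_cores(enumerate_cliques(gw), gw)
        assert [s.members for s in seeds] == [frozenset("abc")]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_seeds_pairwise_disjoint(self, seed):
        ppi = random_ppi(25, 0.3, seed)
        gw = uniform_weighted(ppi)
        seeds = select_seed_cores(enumerate_cliques(gw), gw)
        for s1, s2 in itertools.combinations(seeds, 2):
            assert not (s1.members & s2.members)


class TestCoreGrowth:
    def test_density_formula_boundaries(self, triangle):
        assert cluster_density(frozenset("abc"), triangle) == 1.0
        assert cluster_density(frozenset("a"), triangle) == 0.0

    def test_clique_extension_not_admitted_without_strict_increase(self):
        edges = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        ppi = PPINetwork.from_edges(edges)
        seed = CoreCluster(frozenset("abc"), density=1.0, stage="seed")
        grown = grow_core(seed, ppi)
        assert grown.members == frozenset("abc")  # 1.0 -> 1.0 is no increase

    def test_pendant_neighbor_rejected(self):
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("c", "d")])
        seed = CoreCluster(frozenset("abc"), density=1.0, stage="seed")
        grown = grow_core(seed, ppi)
        assert grown.members == frozenset("abc")  # 4/6 < 1.0

    def test_density_increasing_neighbor_admitted(self):
        # stripped non-clique remnant regains a triangle-closing node
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "d"),
                                     ("b", "d"), ("c", "d")])
        seed = CoreCluster(frozenset("abc"), density=2 / 3, stage="seed")
        grown = grow_core(seed, ppi)
        assert grown.members == frozenset("abcd")  # 5/6 > 2/3


class TestCoreFiltering:
    def test_threshold_boundaries(self, triangle):
        cores = [CoreCluster(frozenset("abc"), density=1.0, stage="core"),
                 CoreCluster(frozenset("xyz"), density=0.667, stage="core")]
        assert len(filter_cores(cores, 0.0)) == 2
        assert len(filter_cores(cores, 1.0)) == 1
        assert len(filter_cores(cores, 0.8)) == 1  # 0.667-density rejected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_cores([], 1.5)


class TestAttachmentScores:
    def test_hyperedge_density_examples(self):
        edges = [(a, b) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        k4 = PPINetwork.from_edges(edges)
        assert hyperedge_density(frozenset("abcd"), k4) == 1.0
        sparse = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        assert hyperedge_density(frozenset("abcd"), sparse) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hyperedge_density(frozenset("a"), k4)

    def test_hyperedge_overlap_examples(self):
        s = frozenset("abcd")
        assert hyperedge_overlap(s, [frozenset("abcd")]) == 1.0
        assert hyperedge_overlap(s, [frozenset("xyz")]) == 0.0
        assert hyperedge_overlap(s, [frozenset("cde")]) == pytest.approx(2 / 5)
        assert hyperedge_overlap(s, []) == 0.0


class TestAttachment:
    def test_vacuous_thresholds_admit_all_adjacent(self):
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("c", "d")])
        cores = [CoreCluster(frozenset("abc"), density=1.0, stage="core")]
        result = attach(cores, ppi, epsilon=0.0, theta=1.0)
        assert result.complexes == [frozenset("abcd")]

    def test_epsilon_one_requires_clique_completion(self):
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("d", "a"), ("d", "b"), ("d", "c"),
                                     ("e", "a")])
        cores = [CoreCluster(frozenset("abc"), density=1.0, stage="core")]
        result = attach(cores, ppi, epsilon=1.0, theta=1.0)
        assert result.complexes == [frozenset("abcd")]  # e does not complete

    def test_sequential_density_gate_is_self_limiting(self):
        # a star of pendants around a triangle: after the first pendant the
        # enlarged set is below eps, so accretion stops
        edges = [("a", "b"), ("b", "c"), ("a", "c")]
        edges += [(p, "a") for p in "uvwxyz"]
        ppi = PPINetwork.from_edges(edges)
        cores = [CoreCluster(frozenset("abc"), density=1.0, stage="core")]
        result = attach(cores, ppi, epsilon=0.7, theta=1.0)
        (cx,) = result.complexes
        assert hyperedge_density(cx, ppi) >= 0.7

    def test_overlap_cap_blocks_sharing(self):
        # two triangles joined through d, which is adjacent to both
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c"),
                                     ("x", "y"), ("y", "z"), ("x", "z"),
                                     ("d", "a"), ("d", "b"), ("d", "c"),
                                     ("d", "x"), ("d", "y"), ("d", "z")])
        cores = [CoreCluster(frozenset("abc"), density=1.0, stage="core"),
                 CoreCluster(frozenset("xyz"), density=1.0, stage="core")]
        open_result = attach(cores, ppi, epsilon=0.7, theta=1.0)
        assert {frozenset("abcd"), frozenset("dxyz")} == set(open_result.complexes)
        # with theta = 0.1 the first admission (abcd) stands, but the second
        # would push Jaccard(dxyz, abcd) = 1/7 above the cap and is blocked
        capped = attach(cores, ppi, epsilon=0.7, theta=0.1)
        assert {frozenset("abcd"), frozenset("xyz")} == set(capped.complexes)


class TestFullPipeline:
    def test_two_planted_cliques_recovered(self):
        edges = []
        left = [f"l{i}" for i in range(6)]
        right = [f"r{i}" for i in range(6)]
        for grp in (left, right):
            edges += [(grp[i], grp[j]) for i in range(6) for j in range(i + 1, 6)]
        edges.append((left[0], right[0]))
        ppi = PPINetwork.from_edges(edges)
        result, report = run_hlca(ppi, seed=0)
        assert {frozenset(left), frozenset(right)} == set(result.complexes)
        assert report["n_complexes"] == 2

    def test_tree_network_gives_no_complexes(self):
        ppi = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d"),
                                     ("b", "e")])
        result, report = run_hlca(ppi, seed=0)
        assert len(result) == 0 and report["n_candidate_cliques"] == 0

    def test_repeat_run_identical(self, ci_fixture):
        ppi, _ = ci_fixture
        r1, _ = run_hlca(ppi, seed=4)
        r2, _ = run_hlca(ppi, seed=4)
        assert r1 == r2
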