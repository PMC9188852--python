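import math
from itertools import combinations

import numpy as np
import pytest

from causalnet.enrichment import (
    EnrichmentConfig,
    bh_qvalues,
    enrich,
    fisher_overlap,
    rwr,
    xd_scores,
)
from causalnet.io_formats import Pathway, StringEdge
from causalnet.network_causal import build_network


def make_network(nodes, weighted_edges):
    """ProteinNetwork from (a, b, weight-in-[0,1]) tuples."""
    edges = [StringEdge(a, b, int(round(w * 1000))) for a, b, w in weighted_edges]
    return build_network(set(nodes), edges, min_score=0)


def oracle_stationary(nodes, weighted_edges, seeds, restart):
    """Dense closed-form stationary vector, built independently of the package.

    s = r (I - (1-r) W)^-1 e with column-normalized W; zero-degree columns
    restart to the seed distribution.
    """
    order = sorted(nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for a, b, w in weighted_edges:
        A[index[a], index[b]] = A[index[b], index[a]] = w
    e = np.zeros(n)
    seeds = sorted(set(seeds) & set(order))
    for s in seeds:
        e[index[s]] = 1.0 / len(seeds)
    W = np.zeros((n, n))
    for j in range(n):
        col = A[:, j].sum()
        W[:, j] = A[:, j] / col if col > 0 else e
    s_vec = restart * np.linalg.solve(np.eye(n) - (1 - restart) * W, e)
    return {node: s_vec[index[node]] for node in order}


def _edge_weight(i, j):
    return 0.25 + ((i + j) % 3) * 0.25  # deterministic weight variety


class TestRwr:
    def test_single_node_seed_scores_one(self):
        network = make_network(["A"], [])
        assert rwr(network, ["A"]) == {"A": pytest.approx(1.0)}

    def test_full_restart_concentrates_on_seeds(self):
        network = make_network(["A", "B", "C"], [("A", "B", 0.9), ("B", "C", 0.9)])
        scores = rwr(network, ["A", "B"], EnrichmentConfig(restart_prob=1.0))
        assert scores["A"] == pytest.approx(0.5)
        assert scores["B"] == pytest.approx(0.5)
        assert scores["C"] == pytest.approx(0.0)

    def test_three_node_path_matches_dense_solve(self):
        nodes = ["A", "B", "C"]
        edges = [("A", "B", 1.0), ("B", "C", 1.0)]
        scores = rwr(make_network(nodes, edges), ["A"])
        expected = oracle_stationary(nodes, edges, ["A"], 0.5)
        for node in nodes:
            assert scores[node] == pytest.approx(expected[node], abs=1e-9)

    def test_exhaustive_small_graphs_match_dense_solve(self):
        """Power iteration equals the closed form on every graph with <= 4 nodes."""
        config = EnrichmentConfig(restart_prob=0.5, tol=1e-12, max_iter=5000)
        for n in range(1, 5):
            nodes = [f"N{i}" for i in range(n)]
            possible = list(combinations(range(n), 2))
            for mask in range(2 ** len(possible)):
                edges = [
                    (nodes[i], nodes[j], _edge_weight(i, j))
                    for k, (i, j) in enumerate(possible)
                    if mask >> k & 1
                ]
                for seeds in ([nodes[0]], nodes):
                    scores = rwr(make_network(nodes, edges), seeds, config)
                    expected = oracle_stationary(nodes, edges, seeds, 0.5)
                    for node in nodes:
                        assert scores[node] == pytest.approx(expected[node], abs=1e-8)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_random_graphs_up_to_eight_nodes_match_dense_solve(self, n):
        rng = np.random.default_rng(n)
        config = EnrichmentConfig(restart_prob=0.3, tol=1e-12, max_iter=5000)
        for _ in range(25):
            nodes = [f"N{i}" for i in range(n)]
            edges = [
                # weights on the same 1/1000 grid the edge-list format stores
                (nodes[i], nodes[j], round(float(rng.uniform(0.1, 1.0)), 3))
                for i, j in combinations(range(n), 2)
                if rng.random() < 0.4
            ]
            n_seeds = int(rng.integers(1, n + 1))
            seeds = [nodes[i] for i in rng.choice(n, size=n_seeds, replace=False)]
            scores = rwr(make_network(nodes, edges), seeds, config)
            expected = oracle_stationary(nodes, edges, seeds, 0.3)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            for node in nodes:
                assert scores[node] == pytest.approx(expected[node], abs=1e-8)

    def test_no_seed_in_network_is_an_error(self):
        with pytest.raises(ValueError):
            rwr(make_network(["A"], []), ["Z"])

    def test_walk_mass_stays_in_seed_component(self):
        # two components; the non-seed component gets zero mass
        network = make_network(
            ["A", "B", "X", "Y"], [("A", "B", 0.9), ("X", "Y", 0.9)]
        )
        scores = rwr(network, ["A"])
        assert scores["X"] == pytest.approx(0.0)
        assert scores["Y"] == pytest.approx(0.0)
        assert scores["A"] + scores["B"] == pytest.approx(1.0)


class TestXdScores:
    def test_identical_pathways_have_zero_deviation(self):
        network = make_network(["A", "B", "C"], [("A", "B", 0.9), ("B", "C", 0.9)])
        node_scores = rwr(network, ["A"])
        pathways = [
            Pathway("P1", "one", frozenset({"A", "B"})),
            Pathway("P2", "two", frozenset({"A", "B"})),
        ]
        xd, _ = xd_scores(node_scores, pathways, network)
        assert xd["P1"] == pytest.approx(0.0)
        assert xd["P2"] == pytest.approx(0.0)

    def test_seed_adjacent_pathway_outranks_distant_pathway(self):
        # 6-node path; seeds at one end
        nodes = [f"N{i}" for i in range(6)]
        edges = [(nodes[i], nodes[i + 1], 0.9) for i in range(5)]
        network = make_network(nodes, edges)
        node_scores = rwr(network, [nodes[0], nodes[1]])
        pathways = [
            Pathway("NEAR", "near", frozenset(nodes[:2])),
            Pathway("FAR", "far", frozenset(nodes[4:])),
        ]
        xd, _ = xd_scores(node_scores, pathways, network)
        assert xd["NEAR"] > xd["FAR"]

    def test_deviations_sum_to_zero_and_skipped_reported(self):
        network = make_network(["A", "B", "C"], [("A", "B", 0.9)])
        node_scores = rwr(network, ["A"])
        pathways = [
            Pathway("P1", "p1", frozenset({"A"})),
            Pathway("P2", "p2", frozenset({"B", "C"})),
            Pathway("P3", "p3", frozenset({"Z"})),  # nothing in network
        ]
        xd, skipped = xd_scores(node_scores, pathways, network)
        assert skipped == ["P3"]
        assert sum(xd.values()) == pytest.approx(0.0, abs=1e-12)

    def test_no_scoreable_pathway_is_an_error(self):
        network = make_network(["A"], [])
        node_scores = rwr(network, ["A"])
        with pytest.raises(ValueError):
            xd_scores(node_scores, [Pathway("P", "p", frozenset({"Z"}))], network)


def oracle_hypergeom_tail(universe_size, n_seeds, n_pathway, overlap):
    """P[X >= overlap] by direct enumeration over possible overlaps."""
    total = 0.0
    for k in range(overlap, min(n_seeds, n_pathway) + 1):
        total += (
            math.comb(n_pathway, k)
            * math.comb(universe_size - n_pathway, n_seeds - k)
            / math.comb(universe_size, n_seeds)
        )
    return total


class TestFisherOverlap:
    def test_printed_worked_example(self):
        universe = [f"U{i}" for i in range(20)]
        seeds = universe[:5]
        pathway = universe[:4]  # overlap 4
        p = fisher_overlap(seeds, pathway, universe)
        assert p == pytest.approx(5 / 4845, rel=1e-9)

    def test_full_overlap_is_degenerate_tail_one(self):
        universe = ["A", "B", "C"]
        assert fisher_overlap(universe, universe, universe) == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"U{i}" for i in range(10)]
        assert fisher_overlap(universe[:3], universe[5:], universe) == pytest.approx(1.0)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_overlap(["A"], ["A"], [])

    def test_agrees_with_enumeration_for_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = int(rng.integers(2, 51))
            universe = [f"U{i}" for i in range(m)]
            n_seeds = int(rng.integers(1, m + 1))
            n_path = int(rng.integers(1, m + 1))
            seeds = [universe[i] for i in rng.choice(m, n_seeds, replace=False)]
            pathway = [universe[i] for i in rng.choice(m, n_path, replace=False)]
            overlap = len(set(seeds) & set(pathway))
            expected = oracle_hypergeom_tail(m, n_seeds, n_path, overlap)
            assert fisher_overlap(seeds, pathway, universe) == pytest.approx(expected, rel=1e-9)


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.02]) == [pytest.approx(0.02)]

    def test_hand_computed_step_up(self):
        assert bh_qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_qvalues([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    def test_order_equivariance(self):
        ps = [0.5, 0.001, 0.2, 0.04]
        qs = bh_qvalues(ps)
        perm = [2, 0, 3, 1]
        qs_perm = bh_qvalues([ps[i] for i in perm])
        assert qs_perm == pytest.approx([qs[i] for i in perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestEnrichEndToEnd:
    def test_planted_pathway_attains_top_xd_and_min_q(self, small_fixture):
        from causalnet import io_formats

        outdir, truth = small_fixture
        edges = io_formats.read_string_edges(outdir / "string_edges.tsv")
        pathways = io_formats.read_gmt(outdir / "pathways.gmt")
        seeds = sorted(p for p, d in truth.planted_significant if d == 2)
        universe = {e.protein_a for e in edges} | {e.protein_b for e in edges} | set(seeds)
        network = build_network(universe, edges, min_score=400)
        results = enrich(network, seeds, pathways)
        assert results[0].pathway_id == truth.enriched_pathway
        assert min(results, key=lambda r: r.q_value).pathway_id == truth.enriched_pathway
        assert results[0].significant_xd
        # q-values never drop below their p-values
        assert all(r.q_value >= r.fisher_p - 1e-12 for r in results)
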