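"""Greedy DAG, levels, transitive reduction, motifs, robustness — vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cpnet import hierarchy_topology as ht

from conftest import edges_df


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _reaches(edges: set, src, dst) -> bool:
    """DFS reachability over an explicit adjacency map."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj.get(u, []))
    return False


def greedy_replay_oracle(edges: pd.DataFrame):
    """Step-by-step replay of the greedy rule with an explicit DFS check."""
    order = edges.sort_values(["pp", "a", "b"], ascending=[False, True, True], kind="mergesort")
    kept, removed = set(), set()
    for row in order.itertuples(index=False):
        if _reaches(kept, row.b, row.a):
            removed.add((row.a, row.b))
        else:
            kept.add((row.a, row.b))
    return kept, removed


def reachability_matrix(nodes, edges: set) -> np.ndarray:
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    R = np.eye(n, dtype=bool)
    for a, b in edges:
        R[idx[a], idx[b]] = True
    for k in range(n):  # Floyd-Warshall closure
        R |= R[:, k][:, None] & R[k, :][None, :]
    return R


def brute_force_motifs(edges: set):
    nodes = sorted({v for e in edges for v in e})
    fb2 = sum(1 for a, b in itertools.combinations(nodes, 2) if (a, b) in edges and (b, a) in edges)
    ff = sum(
        1
        for x, y, z in itertools.permutations(nodes, 3)
        if (x, y) in edges and (y, z) in edges and (x, z) in edges
    )
    fb3 = sum(
        1
        for trip in itertools.combinations(nodes, 3)
        for cyc in (
            [(trip[0], trip[1]), (trip[1], trip[2]), (trip[2], trip[0])],
            [(trip[0], trip[2]), (trip[2], trip[1]), (trip[1], trip[0])],
        )
        if all(e in edges for e in cyc)
    )
    return fb2, fb3, ff


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestGreedyDag:
    def test_two_cycle_keeps_stronger_edge(self):
        layout = ht.greedy_dag(edges_df([("a", "b", 0.99), ("b", "a", 0.95)]))
        assert list(zip(layout.kept["a"], layout.kept["b"])) == [("a", "b")]
        assert list(zip(layout.removed["a"], layout.removed["b"])) == [("b", "a")]

    def test_acyclic_input_unchanged(self):
        edges = edges_df([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)])
        layout = ht.greedy_dag(edges)
        assert layout.removed.empty
        assert len(layout.kept) == 3

    def test_random_tournaments_match_replay_oracle(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 8))
            nodes = [f"n{i}" for i in range(n)]
            rows = []
            for i, j in itertools.combinations(range(n), 2):
                src, dst = (i, j) if rng.uniform() < 0.5 else (j, i)
                rows.append((nodes[src], nodes[dst], float(rng.uniform())))
            edges = edges_df(rows)
            layout = ht.greedy_dag(edges)
            kept_o, removed_o = greedy_replay_oracle(edges)
            assert set(zip(layout.kept["a"], layout.kept["b"])) == kept_o
            assert set(zip(layout.removed["a"], layout.removed["b"])) == removed_o
            # acyclicity of the kept set
            ht.assign_levels(layout.kept)  # raises on a cycle

    def test_removed_edges_each_close_a_cycle(self, rng):
        rows = [
            (f"n{int(rng.integers(0, 10))}", f"n{int(rng.integers(0, 10))}", float(rng.uniform()))
            for _ in range(40)
        ]
        rows = [r for r in rows if r[0] != r[1]]
        layout = ht.greedy_dag(edges_df(rows).drop_duplicates(subset=["a", "b"]))
        kept = set(zip(layout.kept["a"], layout.kept["b"]))
        for a, b in zip(layout.removed["a"], layout.removed["b"]):
            assert _reaches(kept, b, a)  # adding it back would close a cycle


class TestAssignLevels:
    def test_chain(self):
        levels = ht.assign_levels(edges_df([("a", "b", 1), ("b", "c", 1)]))
        assert levels == {"a": 0, "b": 1, "c": 2}

    def test_diamond(self):
        levels = ht.assign_levels(
            edges_df([("a", "b", 1), ("a", "c", 1), ("b", "d", 1), ("c", "d", 1)])
        )
        assert levels["d"] == 2

    def test_shortest_path_wins(self):
        levels = ht.assign_levels(
            edges_df([("a", "b", 1), ("a", "c", 1), ("c", "d", 1), ("b", "d", 1), ("a", "d", 1)])
        )
        assert levels["d"] == 1

    def test_isolated_nodes_are_roots(self):
        levels = ht.assign_levels(edges_df([("a", "b", 1)]), nodes=["a", "b", "z"])
        assert levels["z"] == 0

    def test_cyclic_input_errors(self):
        with pytest.raises(ValueError):
            ht.assign_levels(edges_df([("a", "b", 1), ("b", "a", 1)]))


class TestTransitiveReduction:
    def test_triangle_drops_shortcut(self):
        red = ht.transitive_reduction(edges_df([("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]))
        assert set(zip(red["a"], red["b"])) == {("x", "y"), ("y", "z")}

    def test_chain_unchanged(self):
        edges = edges_df([("a", "b", 1), ("b", "c", 1)])
        red = ht.transitive_reduction(edges)
        assert len(red) == 2

    def test_cyclic_input_errors(self):
        with pytest.raises(ValueError):
            ht.transitive_reduction(edges_df([("a", "b", 1), ("b", "a", 1)]))

    def test_random_dags_reachability_preserved_and_minimal(self, rng):
        for trial in range(200):
            n = int(rng.integers(3, 11))
            nodes = [f"n{i}" for i in range(n)]
            rows = [
                (nodes[i], nodes[j], 1.0)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.uniform() < 0.35
            ]
            if not rows:
                continue
            edges = edges_df(rows)
            red = ht.transitive_reduction(edges)
            full = set(zip(edges["a"], edges["b"]))
            reduced = set(zip(red["a"], red["b"]))
            used = sorted({v for e in full for v in e})
            assert np.array_equal(
                reachability_matrix(used, full), reachability_matrix(used, reduced)
            )
            # minimality: removing any kept edge changes reachability
            for e in reduced:
                smaller = reduced - {e}
                assert not np.array_equal(
                    reachability_matrix(used, reduced), reachability_matrix(used, smaller)
                )

    def test_idempotent(self, rng):
        rows = [(f"n{i}", f"n{j}", 1.0) for i in range(8) for j in range(i + 1, 8) if rng.uniform() < 0.4]
        red1 = ht.transitive_reduction(edges_df(rows))
        red2 = ht.transitive_reduction(red1)
        assert set(zip(red1["a"], red1["b"])) == set(zip(red2["a"], red2["b"]))


class TestClassifyEdges:
    def test_chain_all_one_below(self):
        edges = edges_df([("a", "b", 1), ("b", "c", 1)])
        classes = ht.classify_edges(edges, ht.assign_levels(edges))
        assert (classes == "one-below").all()

    def test_back_edge_one_above(self):
        kept = edges_df([("a", "b", 1), ("b", "c", 1)])
        levels = ht.assign_levels(kept)
        back = edges_df([("c", "b", 1)])
        assert ht.classify_edges(back, levels).iloc[0] == "one-above"

    def test_two_level_skip_back_and_long_forward(self):
        kept = edges_df([("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        levels = ht.assign_levels(kept)
        extra = edges_df([("d", "a", 1), ("a", "c", 1), ("a", "a2", 1)])
        levels["a2"] = 0
        classes = ht.classify_edges(extra, levels)
        assert classes.iloc[0] == "two-or-more-above"
        assert classes.iloc[1] == "long-forward"
        assert classes.iloc[2] == "same-level"


class TestCountMotifs:
    def test_single_ffl(self):
        m = ht.count_motifs(edges_df([("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]))
        assert (m.two_node_feedback, m.three_node_feedback, m.feedforward) == (0, 0, 1)

    def test_three_cycle(self):
        m = ht.count_motifs(edges_df([("x", "y", 1), ("y", "z", 1), ("z", "x", 1)]))
        assert (m.two_node_feedback, m.three_node_feedback, m.feedforward) == (0, 1, 0)

    def test_reciprocal_pair(self):
        m = ht.count_motifs(edges_df([("x", "y", 1), ("y", "x", 1)]))
        assert m.two_node_feedback == 1

    def test_random_graphs_match_brute_force(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 26))
            rows = {
                (f"n{int(rng.integers(0, n))}", f"n{int(rng.integers(0, n))}")
                for _ in range(3 * n)
            }
            rows = [(a, b, 1.0) for a, b in rows if a != b]
            m = ht.count_motifs(edges_df(rows))
            fb2, fb3, ff = brute_force_motifs({(a, b) for a, b, _ in rows})
            assert (m.two_node_feedback, m.three_node_feedback, m.feedforward) == (fb2, fb3, ff)

    def test_permutation_invariance(self, rng):
        rows = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1), ("c", "a", 1)]
        m1 = ht.count_motifs(edges_df(rows))
        relabel = {"a": "z9", "b": "q1", "c": "m5"}
        rows2 = [(relabel[a], relabel[b], p) for a, b, p in rows]
        m2 = ht.count_motifs(edges_df(rows2))
        assert (m1.two_node_feedback, m1.three_node_feedback, m1.feedforward) == (
            m2.two_node_feedback,
            m2.three_node_feedback,
            m2.feedforward,
        )


class TestHubRobustness:
    def test_star_collapse(self):
        edges = edges_df([("hub", f"t{i}", 1.0) for i in range(10)])
        res = ht.hub_robustness(edges, k_max=1)
        assert res.loc[0, "removed"] == "hub"
        assert res.loc[0, "relative_lcc"] == pytest.approx(1 / 11)

    def test_two_disjoint_chains(self):
        edges = edges_df(
            [("a1", "a2", 1.0), ("a1", "a3", 1.0), ("b1", "b2", 1.0)]
        )
        res = ht.hub_robustness(edges, k_max=1)
        # a1 is the top hub; the b-chain stays intact
        assert res.loc[0, "removed"] == "a1"
        assert res.loc[0, "relative_lcc"] == pytest.approx(2 / 5)

    def test_random_network_matches_component_oracle(self, rng):
        rows = {
            (f"n{int(rng.integers(0, 15))}", f"n{int(rng.integers(0, 15))}") for _ in range(30)
        }
        rows = [(a, b, 1.0) for a, b in rows if a != b]
        edges = edges_df(rows)
        res = ht.hub_robustness(edges, k_max=3)

        # union-find oracle
        def lcc_after_removal(removed: set) -> int:
            nodes = sorted({v for a, b, _ in rows for v in (a, b)} - removed)
            parent = {v: v for v in nodes}

            def find(v):
                while parent[v] != v:
                    parent[v] = parent[parent[v]]
                    v = parent[v]
                return v

            for a, b, _ in rows:
                if a in removed or b in removed:
                    continue
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
            from collections import Counter

            return max(Counter(find(v) for v in nodes).values(), default=0)

        n0 = len({v for a, b, _ in rows for v in (a, b)})
        removed = set()
        for _, row in res.iterrows():
            removed.add(row["removed"])
            assert row["relative_lcc"] == pytest.approx(lcc_after_removal(removed) / n0)


class TestDegreeDistributions:
    def test_empty_network(self):
        deg = ht.degree_distributions(pd.DataFrame(columns=["a", "b", "pp"]))
        assert deg.empty

    def test_degree_sums_equal_edge_count(self, rng):
        rows = {(f"n{int(rng.integers(0, 12))}", f"n{int(rng.integers(0, 12))}") for _ in range(25)}
        rows = [(a, b, 1.0) for a, b in rows if a != b]
        deg = ht.degree_distributions(edges_df(rows))
        assert deg["out_degree"].sum() == len(rows)
        assert deg["in_degree"].sum() == len(rows)

    def test_fixture_hand_count(self):
        deg = ht.degree_distributions(edges_df([("a", "b", 1), ("a", "c", 1), ("b", "c", 1)]))
        d = deg.set_index("node")
        assert d.loc["a", "out_degree"] == 2 and d.loc["a", "in_degree"] == 0
        assert d.loc["c", "in_degree"] == 2
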