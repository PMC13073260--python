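"""S_AB separation: worked path example, brute-force oracle, properties."""

import networkx as nx
import numpy as np
import pytest

from revnet import (
    Module,
    between_distance,
    separation,
    separation_matrix,
    within_distance,
)

from conftest import bfs_oracle, random_graph


def oracle_within(g, nodes):
    nodes = sorted(nodes)
    if len(nodes) == 1:
        return 0.0
    vals = []
    for v in nodes:
        dist = bfs_oracle(g, v)
        vals.append(min(dist.get(u, np.inf) for u in nodes if u != v))
    return float(np.mean(vals))


def oracle_between(g, a, b):
    def contrib(v, other):
        targets = sorted(set(other) - {v})
        if not targets:
            return 0.0
        dist = bfs_oracle(g, v)
        return min(dist.get(u, np.inf) for u in targets)

    vals = [contrib(v, b) for v in sorted(a)]
    vals += [contrib(v, a) for v in sorted(b)]
    return float(np.mean(vals))


class TestWorkedExamples:
    def test_path_graph_within(self, path6):
        assert within_distance(path6, {"1", "2"}) == 1.0

    def test_path_graph_between(self, path6):
        assert between_distance(path6, {"1", "2"}, {"5", "6"}) == 3.5

    def test_path_graph_separation(self, path6):
        assert separation(path6, {"1", "2"}, {"5", "6"}) == 2.5

    def test_clique_module_within_one(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, str)
        assert within_distance(g, {"0", "1", "2"}) == 1.0

    def test_singleton_convention(self, path6):
        assert within_distance(path6, {"3"}) == 0.0

    def test_identical_modules_zero(self, path6):
        assert separation(path6, {"2", "3"}, {"2", "3"}) == 0.0

    def test_adjacent_singletons(self, path6):
        assert between_distance(path6, {"1"}, {"2"}) == 1.0

    def test_interleaved_halves_of_clique(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, str)
        assert separation(g, {"0", "2", "4"}, {"1", "3", "5"}) == 0.0

    def test_missing_node_error(self, path6):
        with pytest.raises(ValueError, match="absent"):
            within_distance(path6, {"1", "zz"})


class TestOracleEquivalence:
    def test_random_graphs_match_bfs_oracle(self):
        """100 seeded random graphs (<=8 nodes): exact distance agreement."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            g = random_graph(rng)
            nodes = sorted(g.nodes)
            a = set(rng.choice(nodes, size=max(1, len(nodes) // 2), replace=False))
            b = set(rng.choice(nodes, size=max(1, len(nodes) // 3), replace=False))
            ow, ob = oracle_within(g, a), oracle_between(g, a, b)
            if not (np.isfinite(ow) and np.isfinite(ob) and np.isfinite(oracle_within(g, b))):
                continue  # disconnected draw: distances undefined
            assert within_distance(g, a) == ow
            assert between_distance(g, a, b) == ob
            assert separation(g, a, b) == pytest.approx(
                ob - 0.5 * (ow + oracle_within(g, b))
            )
            checked += 1

    def test_symmetry(self, path6):
        a, b = {"1", "3"}, {"4", "6"}
        assert separation(path6, a, b) == separation(path6, b, a)

    def test_self_separation_zero_on_random_connected_modules(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_graph(rng, n_max=8, p=0.6)
            if not nx.is_connected(g) or g.number_of_nodes() < 2:
                continue
            k = int(rng.integers(2, g.number_of_nodes() + 1))
            mod = set(rng.choice(sorted(g.nodes), size=k, replace=False))
            assert separation(g, mod, mod) == 0.0

    def test_moving_module_along_path_increases_separation(self):
        g = nx.path_graph(12)
        g = nx.relabel_nodes(g, str)
        a = {"0", "1"}
        prev = separation(g, a, {"4", "5"})
        for shift in (5, 6, 7):
            cur = separation(g, a, {str(shift), str(shift + 1)})
            assert cur > prev
            prev = cur


class TestSeparationMatrix:
    def _mods(self, label_prefix, sets):
        return [
            Module(label=f"{label_prefix}{i+1}", members=tuple(sorted(s)), score=1.0,
                   seed=sorted(s)[0])
            for i, s in enumerate(sets)
        ]

    def test_single_pair_is_best(self, path6):
        res = separation_matrix(
            path6, self._mods("A", [{"1", "2"}]), self._mods("B", [{"5", "6"}])
        )
        assert res.best_pair == ("A1", "B1")
        assert res.best_value == 2.5

    def test_interleaved_pair_attains_minimum_and_is_negative(self):
        """Gene/protein modules sharing one dense block (complete bipartite
        g-p connections) separate less than either does from a far pair."""
        g = nx.complete_bipartite_graph(4, 4)
        g = nx.relabel_nodes(
            g, lambda i: f"g{i}" if i < 4 else f"p{i - 4}"
        )
        far = nx.relabel_nodes(nx.path_graph(4), lambda i: f"z{i}")
        g = nx.compose(g, far)
        g.add_edge("g0", "z0")
        mods_a = self._mods("A", [{f"g{i}" for i in range(4)}, {"z0", "z1"}])
        mods_b = self._mods("B", [{f"p{i}" for i in range(4)}, {"z2", "z3"}])
        res = separation_matrix(g, mods_a, mods_b)
        # genes reach proteins in 1 hop but each other only in 2: S = 1 - 2
        assert res.s_ab.at["A1", "B1"] == -1.0
        assert res.best_pair == ("A1", "B1")
        assert res.best_value < 0

    def test_unreachable_modules_flagged_not_imputed(self):
        g = nx.compose(
            nx.relabel_nodes(nx.complete_graph(4), lambda i: f"a{i}"),
            nx.relabel_nodes(nx.complete_graph(3), lambda i: f"z{i}"),
        )
        mods_a = self._mods("A", [{"a0", "a1"}, {"z0", "z1"}])
        mods_b = self._mods("B", [{"a2", "a3"}])
        res = separation_matrix(g, mods_a, mods_b)
        assert "A2" in res.unevaluable
        assert list(res.s_ab.index) == ["A1"]
        assert np.isfinite(res.s_ab.to_numpy(float)).all()

    def test_empty_module_set_rejected(self, path6):
        with pytest.raises(ValueError, match="non-empty"):
            separation_matrix(path6, [], self._mods("B", [{"1"}]))
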