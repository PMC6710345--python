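"""Co-occurrence network: thresholding, modules, hubs, exports."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilrisknet import network as net
from soilrisknet.errors import ConfigurationError, ValidationError


def _random_table(rng, n=20, k=6, correlated=True):
    base = rng.normal(size=n)
    cols = {}
    for i in range(k):
        noise = rng.normal(size=n)
        cols[f"v{i}"] = base + 0.8 * noise if correlated and i % 2 == 0 else noise
    return pd.DataFrame(cols)


def _cats(table):
    return {c: "ARG" for c in table.columns}


class TestBuildNetwork:
    def test_no_strong_pair_gives_empty_edge_set(self, rng):
        table = _random_table(rng, correlated=False)
        g = net.build_network(table, _cats(table), rho_threshold=0.999)
        assert g.number_of_nodes() == 6
        assert g.number_of_edges() == 0

    def test_exact_threshold_excluded(self):
        # ranks engineered so Spearman rho is exactly 0.6 (sum d^2 = 8, n=5)
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 2.0, 1.0, 4.0, 5.0]
        assert sps.spearmanr(x, y).statistic == pytest.approx(0.6)
        table = pd.DataFrame({"a": x, "b": y})
        g = net.build_network(table, {"a": "RI", "b": "ARG"},
                              rho_threshold=0.6, p_threshold=1.0)
        assert g.number_of_edges() == 0
        g2 = net.build_network(table, {"a": "RI", "b": "ARG"},
                               rho_threshold=0.59, p_threshold=1.0)
        assert g2.number_of_edges() == 1

    def test_edges_match_bruteforce_enumeration(self, rng):
        table = _random_table(rng, n=16, k=5)
        g = net.build_network(table, _cats(table))
        expected = set()
        for a, b in itertools.combinations(table.columns, 2):
            r = sps.spearmanr(table[a], table[b])
            if abs(r.statistic) > 0.6 and r.pvalue < 0.05:
                expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in g.edges} == expected

    def test_threshold_monotonicity(self, rng):
        table = _random_table(rng, n=25, k=8)
        base = net.build_network(table, _cats(table), rho_threshold=0.3)
        edges = lambda g: {frozenset(e) for e in g.edges}
        tighter_rho = net.build_network(table, _cats(table), rho_threshold=0.5)
        tighter_p = net.build_network(table, _cats(table), rho_threshold=0.3,
                                      p_threshold=0.01)
        assert edges(tighter_rho) <= edges(base)
        assert edges(tighter_p) <= edges(base)

    def test_rank_invariance(self, rng):
        table = _random_table(rng, n=18, k=5)
        shifted = table - table.min() + 1.0
        transformed = shifted.apply(np.log)
        g1 = net.build_network(shifted, _cats(table))
        g2 = net.build_network(transformed, _cats(table))
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        for u, v in g1.edges:
            assert g1[u][v]["rho"] == pytest.approx(g2[u][v]["rho"], abs=1e-12)

    def test_constant_variable_excluded_with_warning(self, rng, caplog):
        table = _random_table(rng, k=4)
        table["flat"] = 1.0
        cats = _cats(table)
        with caplog.at_level("WARNING", logger="soilrisknet.network"):
            g = net.build_network(table, cats)
        assert "flat" not in g
        assert any("flat" in r.message for r in caplog.records)

    def test_untagged_variable_rejected(self, rng):
        table = _random_table(rng, k=3)
        with pytest.raises(ValidationError, match="v2"):
            net.build_network(table, {"v0": "RI", "v1": "ARG"})

    def test_edge_attributes(self, rng):
        table = _random_table(rng, n=30, k=4)
        g = net.build_network(table, _cats(table), rho_threshold=0.2)
        for u, v, d in g.edges(data=True):
            assert d["sign"] == ("+" if d["rho"] > 0 else "-")
            assert d["weight"] == pytest.approx(abs(d["rho"]))
            assert 0 <= d["p"] < 0.05


def _triangle_pair():
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for u, v in itertools.combinations(tri, 2):
            g.add_edge(u, v, rho=0.9, p=0.01, sign="+", weight=0.9)
    for n_ in g.nodes:
        g.nodes[n_]["category"] = "ARG"
    return g


class TestModules:
    def test_two_disjoint_triangles(self):
        g = _triangle_pair()
        assignment = net.detect_modules(g, seed=1)
        assert len(set(assignment.values())) == 2
        assert assignment["a"] == assignment["b"] == assignment["c"]
        assert assignment["x"] == assignment["y"] == assignment["z"]

    def test_empty_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde", category="MRG")
        assignment = net.detect_modules(g, seed=0)
        assert len(set(assignment.values())) == 5

    def test_deterministic_for_fixed_seed(self, rng):
        table = _random_table(rng, n=25, k=8)
        g = net.build_network(table, _cats(table), rho_threshold=0.3)
        a1 = net.detect_modules(g, seed=42)
        a2 = net.detect_modules(g.copy(), seed=42)
        assert a1 == a2

    def test_greedy_method_agrees_on_clean_structure(self):
        g = _triangle_pair()
        assignment = net.detect_modules(g, method="greedy")
        assert len(set(assignment.values())) == 2

    def test_partition_beats_trivial_modularity(self, rng):
        table = _random_table(rng, n=25, k=8)
        g = net.build_network(table, _cats(table), rho_threshold=0.3)
        if g.number_of_edges() == 0:
            pytest.skip("no edges in random draw")
        assignment = net.detect_modules(g, seed=0)
        parts = {}
        for node, mid in assignment.items():
            parts.setdefault(mid, set()).add(node)
        q = nx.community.modularity(g, parts.values(), weight="weight")
        q_trivial = nx.community.modularity(g, [set(g.nodes)], weight="weight")
        assert q >= q_trivial - 1e-12

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            net.detect_modules(_triangle_pair(), method="magic")


class TestHubs:
    def test_star_center_is_hub(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 0.8, "rho")
        nx.set_edge_attributes(g, 0.8, "weight")
        nx.set_node_attributes(g, "ARG", "category")
        nx.set_node_attributes(g, 0, "module")
        hubs = net.find_hubs(g)
        assert hubs == {0: 0}
        assert g.nodes[0]["hub"]

    def test_degree_tie_broken_by_rho_sum(self):
        g = nx.Graph()
        # b and c both have degree 2; c's |rho| sum is larger
        g.add_edge("a", "b", rho=0.7)
        g.add_edge("b", "d", rho=0.61)
        g.add_edge("a", "c", rho=0.9)
        g.add_edge("c", "d", rho=0.9)
        nx.set_node_attributes(g, 0, "module")
        assert net.find_hubs(g) == {0: "c"}

    def test_full_tie_breaks_lexicographically(self):
        g = nx.cycle_graph(["b", "a", "c"])  # symmetric triangle
        nx.set_edge_attributes(g, 0.8, "rho")
        nx.set_node_attributes(g, 0, "module")
        assert net.find_hubs(g) == {0: "a"}

    def test_matches_bruteforce_degree_scan(self, rng):
        table = _random_table(rng, n=30, k=10)
        g = net.build_network(table, _cats(table), rho_threshold=0.3)
        net.detect_modules(g, seed=3)
        hubs = net.find_hubs(g)
        for mid, hub in hubs.items():
            members = [n_ for n_, d in g.nodes(data=True) if d["module"] == mid]
            degs = {
                n_: sum(1 for nbr in g[n_] if g.nodes[nbr]["module"] == mid)
                for n_ in members
            }
            assert degs[hub] == max(degs.values())

    def test_singleton_module_has_no_hub(self):
        g = nx.Graph()
        g.add_node("lonely", category="MGE", module=0)
        assert net.find_hubs(g) == {}
        assert not g.nodes["lonely"]["hub"]

    def test_requires_modules(self):
        g = _triangle_pair()
        with pytest.raises(ValidationError):
            net.find_hubs(g)


class TestExport:
    def _network(self, rng):
        table = _random_table(rng, n=25, k=8)
        g = net.build_network(table, _cats(table), rho_threshold=0.3)
        net.detect_modules(g, seed=5)
        net.find_hubs(g)
        return g

    @pytest.mark.parametrize("fmt,reader", [
        ("graphml", nx.read_graphml), ("gexf", nx.read_gexf)
    ])
    def test_round_trip(self, rng, tmp_path, fmt, reader):
        g = self._network(rng)
        path = tmp_path / f"net.{fmt}"
        net.export_network(g, path, fmt)
        back = reader(str(path))
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        for u, v, d in g.edges(data=True):
            assert float(back[u][v]["rho"]) == pytest.approx(d["rho"], abs=1e-12)
            assert float(back[u][v]["p"]) == pytest.approx(d["p"], abs=1e-12)
        for n_, d in g.nodes(data=True):
            assert back.nodes[n_]["category"] == d["category"]
            assert int(back.nodes[n_]["module"]) == d["module"]

    def test_edge_list_parse_back(self, rng, tmp_path):
        g = self._network(rng)
        path = tmp_path / "edges.tsv"
        net.export_network(g, path, "edge-list")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == g.number_of_edges()
        assert set(df.columns) == {"source", "target", "rho", "p", "sign"}

    def test_empty_network_is_valid_file(self, tmp_path):
        g = nx.Graph()
        g.add_nodes_from("ab", category="RI", module=0, hub=False)
        path = tmp_path / "empty.graphml"
        net.export_network(g, path, "graphml")
        assert set(nx.read_graphml(str(path)).nodes) == {"a", "b"}

    def test_unknown_format_rejected(self, rng, tmp_path):
        with pytest.raises(ConfigurationError):
            net.export_network(nx.Graph(), tmp_path / "x", "dot")

    def test_category_counts_preserved(self, rng, tmp_path):
        # a 37-node panel: 8 risk components, 10 MRGs, 17 ARGs, 2 MGEs
        cats = (["RI"] * 8 + ["MRG"] * 10 + ["ARG"] * 17 + ["MGE"] * 2)
        g = nx.Graph()
        for i, c in enumerate(cats):
            g.add_node(f"n{i}", category=c, module=0, hub=False)
        path = tmp_path / "cats.graphml"
        net.export_network(g, path, "graphml")
        back = nx.read_graphml(str(path))
        counts = pd.Series([d["category"] for _, d in back.nodes(data=True)]).value_counts()
        assert counts.to_dict() == {"ARG": 17, "MRG": 10, "RI": 8, "MGE": 2}


def test_node_and_edge_tables(rng):
    table = _random_table(rng, n=25, k=6)
    g = net.build_network(table, _cats(table), rho_threshold=0.3)
    net.detect_modules(g, seed=0)
    net.find_hubs(g)
    nodes = net.node_table(g)
    edges = net.edge_table(g)
    assert len(nodes) == g.number_of_nodes()
    assert len(edges) == g.number_of_edges()
    assert (nodes.set_index("id")["degree"] == pd.Series(dict(g.degree()))).all()
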