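"""Network construction, refinement, components and topology."""

import networkx as nx
import numpy as np
import pytest

from modnet import datasets
from modnet.netbuild import (
    InteractionEdge,
    build_fi_network,
    build_subject_ppi,
    giant_component,
    intersect_networks,
    read_mitab,
    topology,
    write_mitab,
)


def undirected(*pairs):
    return [InteractionEdge(a, b) for a, b in pairs]


def directed(*pairs):
    return [InteractionEdge(a, b, directed=True) for a, b in pairs]


class TestMitab:
    def _line(self, a, b, tax_a=9606, tax_b=9606):
        cols = [
            f"uniprotkb:{a}_X", f"uniprotkb:{b}_X", "-", "-",
            f"uniprotkb:{a}(gene name)", f"uniprotkb:{b}(gene name)",
            "-", "-", "-",
            f"taxid:{tax_a}(x)", f"taxid:{tax_b}(y)",
            "-", "-", "intact:EBI-1", "-",
        ]
        return "\t".join(cols)

    def test_taxon_filter(self, tmp_path):
        p = tmp_path / "x.mitab"
        p.write_text(self._line("A", "B") + "\n" +
                     self._line("A", "C", tax_b=10090) + "\n")
        edges = read_mitab(str(p))
        assert len(edges) == 1
        assert {edges[0].source, edges[0].target} == {"A", "B"}

    def test_duplicate_orientations_collapse(self, tmp_path):
        p = tmp_path / "x.mitab"
        p.write_text(self._line("A", "B") + "\n" + self._line("B", "A") + "\n")
        assert len(read_mitab(str(p))) == 1

    def test_write_read_roundtrip(self, tmp_path):
        edges = undirected(("A", "B"), ("B", "C"), ("C", "D"))
        p = tmp_path / "r.mitab"
        write_mitab(edges, str(p))
        back = read_mitab(str(p))
        assert {frozenset((e.source, e.target)) for e in back} == \
            {frozenset((e.source, e.target)) for e in edges}


class TestSubjectPpi:
    def test_induced_subgraph_definition(self):
        g = build_subject_ppi({"A", "B", "C"},
                              undirected(("A", "B"), ("B", "X")))
        assert set(g.nodes) == {"A", "B", "C"}
        assert set(map(frozenset, g.edges)) == {frozenset(("A", "B"))}

    def test_disconnected_genes_stay_as_singletons(self):
        g = build_subject_ppi({"P", "Q"}, undirected(("A", "B")))
        assert set(g.nodes) == {"P", "Q"}
        assert g.number_of_edges() == 0

    def test_matches_brute_force_pair_loop(self, small_bundle, rng):
        edges = small_bundle.interactome
        genes = set(rng.choice(small_bundle.genes, size=200, replace=False))
        g = build_subject_ppi(genes, edges)
        edge_set = {frozenset((e.source, e.target)) for e in edges}
        expected = set()
        gl = sorted(genes)
        for i, a in enumerate(gl):
            for b in gl[i + 1:]:
                if frozenset((a, b)) in edge_set:
                    expected.add(frozenset((a, b)))
        assert set(map(frozenset, g.edges)) == expected
        assert set(g.nodes) == genes  # never a node outside the input


class TestGiantComponent:
    def test_binning_of_small_components(self):
        g = nx.path_graph(5)
        g.add_edge("p1", "p2")
        g.add_node("lonely")
        d = giant_component(g)
        assert d.giant.number_of_nodes() == 5
        assert (d.n_pairs, d.n_singletons, d.n_triads) == (1, 1, 0)
        assert not d.secondary_clusters

    def test_connected_network_is_all_giant(self):
        g = nx.complete_graph(6)
        d = giant_component(g)
        assert d.giant.number_of_nodes() == 6
        assert d.counts()["n_singletons"] == 0

    def test_empty_network(self):
        d = giant_component(nx.Graph())
        assert d.giant.number_of_nodes() == 0

    def test_matches_union_find_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(2**31)))
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for u, v in g.edges():
                parent[find(u)] = find(v)
            sizes = {}
            for i in range(n):
                sizes[find(i)] = sizes.get(find(i), 0) + 1
            counts = sorted(sizes.values(), reverse=True)
            d = giant_component(g)
            assert d.giant.number_of_nodes() == counts[0]
            assert d.n_singletons == sum(1 for c in counts[1:] if c == 1)
            assert d.n_pairs == sum(1 for c in counts[1:] if c == 2)
            assert d.n_triads == sum(1 for c in counts[1:] if c == 3)
            total = (d.giant.number_of_nodes()
                     + sum(c.number_of_nodes() for c in d.secondary_clusters)
                     + 3 * d.n_triads + 2 * d.n_pairs + d.n_singletons)
            assert total == n

    def test_invariant_under_relabeling(self, rng):
        g = nx.gnp_random_graph(15, 0.1, seed=3)
        mapping = dict(zip(g.nodes, rng.permutation([f"n{i}" for i in range(15)])))
        h = nx.relabel_nodes(g, mapping)
        dg, dh = giant_component(g), giant_component(h)
        assert dg.counts()["giant_nodes"] == dh.counts()["giant_nodes"]
        assert (dg.n_triads, dg.n_pairs, dg.n_singletons) == \
            (dh.n_triads, dh.n_pairs, dh.n_singletons)


class TestFiNetwork:
    def test_minimal_linker_case(self):
        g = build_fi_network({"A": "up", "B": "down"},
                             directed(("A", "L"), ("L", "B")))
        assert set(g.nodes) == {"A", "B", "L"}
        assert g.nodes["L"]["role"] == "linker"
        assert g.nodes["A"]["direction"] == "up"

    def test_connected_degs_need_no_linkers(self):
        g = build_fi_network({"A": "up", "B": "down"},
                             directed(("A", "B"), ("A", "L"), ("L", "B")))
        assert set(g.nodes) == {"A", "B"}

    def test_every_linker_touches_two_degs(self, small_bundle, rng):
        de_names = [g for g, _ in small_bundle.truth.de_genes]
        degs = {g: "up" for g in rng.choice(de_names, size=min(50, len(de_names)),
                                            replace=False)}
        g = build_fi_network(degs, small_bundle.fi_db)
        und = g.to_undirected(as_view=True)
        adj = {}
        for e in small_bundle.fi_db:
            adj.setdefault(e.source, set()).add(e.target)
            adj.setdefault(e.target, set()).add(e.source)
        for node, data in g.nodes(data=True):
            if data["role"] == "linker":
                assert len(adj[node] & set(degs)) >= 2


class TestTopology:
    def test_star_degrees(self):
        g = nx.DiGraph((f"c", f"l{i}") for i in range(5))
        t = topology(g).set_index("gene")
        assert t.loc["c", "out_degree"] == 5
        assert t.loc["c", "in_degree"] == 0
        assert t.loc["c", "edge_count"] == 5

    def test_case_study_hub_table_consistency(self):
        """In the published hub table every edge count equals
        in-degree + out-degree (e.g. the EP300 row: 24 + 91 = 115)."""
        hubs = datasets.load_fi_core_genes()
        assert (hubs["edge_count"] ==
                hubs["in_degree"] + hubs["out_degree"]).all()
        ep300 = hubs.set_index("gene_symbol").loc["EP300"]
        assert tuple(ep300[["edge_count", "in_degree", "out_degree"]]) == \
            (115, 24, 91)

    def test_matches_brute_force_edge_scan(self, rng):
        g = nx.gnp_random_graph(25, 0.15, directed=True,
                                seed=int(rng.integers(2**31)))
        t = topology(g).set_index("gene")
        for node in g.nodes:
            ind = sum(1 for u, v in g.edges if v == node)
            outd = sum(1 for u, v in g.edges if u == node)
            assert t.loc[node, "in_degree"] == ind
            assert t.loc[node, "out_degree"] == outd
        assert t["in_degree"].sum() == t["out_degree"].sum() == g.number_of_edges()

    def test_ranking_deterministic(self):
        g = nx.DiGraph([("B", "A"), ("C", "A")])
        t = topology(g)
        assert list(t["gene"]) == ["A", "B", "C"]  # ties lexicographic


class TestIntersect:
    def test_self_intersection_identity(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        h = intersect_networks(g, g, "a")
        assert set(h.nodes) == set(g.nodes)
        assert set(map(frozenset, h.edges)) == set(map(frozenset, g.edges))

    def test_disjoint_nodes_empty(self):
        a, b = nx.Graph([("A", "B")]), nx.Graph([("X", "Y")])
        with pytest.warns(UserWarning):
            h = intersect_networks(a, b, "a")
        assert h.number_of_nodes() == 0

    def test_node_set_oracle_and_edge_provenance(self, rng):
        for _ in range(20):
            a = nx.gnp_random_graph(20, 0.2, seed=int(rng.integers(2**31)))
            b = nx.gnp_random_graph(30, 0.1, seed=int(rng.integers(2**31)))
            h = intersect_networks(a, b, "a")
            assert set(h.nodes) == set(a.nodes) & set(b.nodes)
            for u, v in h.edges:
                assert a.has_edge(u, v)
            # node-set commutativity
            h2 = intersect_networks(b, a, "a")
            assert set(h.nodes) == set(h2.nodes)
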