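import networkx as nx
import numpy as np
import pytest

from kgexplore.anatomy import (AnatomyEdge, BroaderGraph, check_acyclic,
                               descendants, min_broader_path, split_serialize,
                               to_broader)
from kgexplore.examples import (SKIN_OF_BODY, SKIN_OF_LIMB, ZONE_OF_SKIN,
                                skin_minimal_edges)
from kgexplore.namespaces import CurieRef

from conftest import random_dag


def _n(i):
    return CurieRef("obo", f"N{i:03d}")


class TestToBroader:
    def test_partof_and_subclassof_edges_tagged_by_source(self):
        g = skin_minimal_edges()
        assert g.from_partof == {(ZONE_OF_SKIN, SKIN_OF_BODY)}
        assert g.from_subclassof == {(SKIN_OF_LIMB, ZONE_OF_SKIN)}

    def test_empty_input(self):
        g = to_broader([])
        assert g.logical_edges() == set()

    def test_edge_count_preserved_for_duplicate_free_input(self):
        rng = np.random.default_rng(5)
        edges = []
        seen = set()
        for _ in range(60):
            a, b = rng.integers(0, 40, size=2)
            rel = "partOf" if rng.uniform() < 0.5 else "subClassOf"
            if a != b and (a, b, rel) not in seen:
                seen.add((a, b, rel))
                edges.append(AnatomyEdge(_n(a), rel, _n(b)))
        g = to_broader(edges)
        assert len(g.from_partof) + len(g.from_subclassof) == len(edges)

    def test_duplicates_collapse_within_a_tag(self):
        e = AnatomyEdge(_n(1), "partOf", _n(2))
        g = to_broader([e, e, e])
        assert len(g.from_partof) == 1

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            AnatomyEdge(_n(1), "partOf", _n(1))
        with pytest.raises(ValueError):
            AnatomyEdge(_n(1), "sibling_of", _n(2))


class TestSplitSerialize:
    def test_one_triple_per_file_on_the_two_edge_graph(self):
        partof, subclassof = split_serialize(skin_minimal_edges())
        assert partof.count(" skos:broader ") == 1
        assert subclassof.count(" skos:broader ") == 1
        assert "UBERON_0000014 skos:broader obo:UBERON_0002097" in partof
        assert "UBERON_0001419 skos:broader obo:UBERON_0000014" in subclassof

    def test_empty_graph_yields_prefix_only_documents(self):
        partof, subclassof = split_serialize(BroaderGraph())
        for text in (partof, subclassof):
            body = [l for l in text.splitlines() if l and not l.startswith("@prefix")]
            assert body == []

    def test_counts_split_by_tag(self):
        rng = np.random.default_rng(11)
        g = BroaderGraph()
        pairs = set()
        while len(pairs) < 50:
            a, b = rng.integers(0, 200, size=2)
            if a != b:
                pairs.add((_n(a), _n(b)))
        pairs = sorted(pairs, key=str)
        g.from_partof = set(pairs[:30])
        g.from_subclassof = set(pairs[30:])
        partof, subclassof = split_serialize(g)
        assert partof.count(" skos:broader ") == 30
        assert subclassof.count(" skos:broader ") == 20

    def test_serialization_is_sorted_and_deterministic(self):
        g = skin_minimal_edges()
        assert split_serialize(g) == split_serialize(g)


class TestDescendants:
    def test_two_edge_graph_closure_contains_all_three_terms(self):
        got = descendants(skin_minimal_edges(), SKIN_OF_BODY)
        assert got == {SKIN_OF_BODY, ZONE_OF_SKIN, SKIN_OF_LIMB}

    def test_leaf_reflexive_closure_is_itself(self):
        leaf = CurieRef("obo", "NOWHERE")
        assert descendants(skin_minimal_edges(), leaf) == {leaf}

    def test_nonreflexive_equals_reflexive_minus_root(self):
        g = skin_minimal_edges()
        assert descendants(g, SKIN_OF_BODY, reflexive=False) == \
            descendants(g, SKIN_OF_BODY) - {SKIN_OF_BODY}

    def test_matches_reverse_reachability_on_random_dags(self):
        """descendants == networkx ancestors (reverse reachability) on 100 DAGs."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(2, 201))
            g, nodes = random_dag(rng, n)
            digraph = g.to_networkx()
            root = nodes[int(rng.integers(0, n))]
            expected = (nx.ancestors(digraph, root) if root in digraph else set()) | {root}
            assert descendants(g, root) == expected

    def test_cycles_tolerated(self):
        g = BroaderGraph(from_partof={(_n(1), _n(2)), (_n(2), _n(1))})
        assert descendants(g, _n(1)) == {_n(1), _n(2)}


class TestMinBroaderPath:
    def test_skin_of_limb_to_skin_of_body_is_two_steps(self):
        assert min_broader_path(skin_minimal_edges(), SKIN_OF_LIMB, SKIN_OF_BODY) == 2

    def test_identity_is_zero(self):
        assert min_broader_path(skin_minimal_edges(), SKIN_OF_BODY, SKIN_OF_BODY) == 0

    def test_wrong_direction_is_absent(self):
        assert min_broader_path(skin_minimal_edges(), SKIN_OF_BODY, SKIN_OF_LIMB) is None

    def test_matches_networkx_shortest_path_on_random_dags(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            g, nodes = random_dag(rng, int(rng.integers(5, 80)))
            digraph = g.to_networkx()
            for _ in range(10):
                a = nodes[int(rng.integers(0, len(nodes)))]
                b = nodes[int(rng.integers(0, len(nodes)))]
                try:
                    expected = nx.shortest_path_length(digraph, a, b)
                except (nx.NetworkXNoPath, nx.NodeNotFound):
                    expected = None
                assert min_broader_path(g, a, b) == expected


class TestCheckAcyclic:
    def test_skin_graph_is_acyclic(self):
        assert check_acyclic(skin_minimal_edges()).is_acyclic

    def test_two_cycle_reported(self):
        g = BroaderGraph(from_subclassof={(_n(1), _n(2)), (_n(2), _n(1))})
        report = check_acyclic(g)
        assert not report.is_acyclic
        assert len(report.cycles[0]) == 2

    def test_random_dag_is_acyclic(self):
        g, _ = random_dag(np.random.default_rng(7), 100)
        assert check_acyclic(g).is_acyclic
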