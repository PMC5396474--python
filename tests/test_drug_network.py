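"""Drug-target mapping, network propagation and response direction."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from tarsnp.classify import EffectClass, make_call
from tarsnp.drug_network import (
    PathwayGraph,
    load_pathways,
    map_direct_targets,
    pathway_indirect_targets,
    ppi_indirect_targets,
    predict_response_direction,
    shortest_path_length,
)


def call(gene, snp="rs1", t_wt=-8.0, t_var=None):
    return make_call(snp, gene, "mir-x", t_wt, t_var)


def drug_map(rows):
    return pd.DataFrame(rows, columns=["drug_id", "drug_name", "gene_id"])


class TestShortestPathLength:
    def test_trivial_distances(self):
        g = nx.path_graph(["a", "b", "c"])
        assert shortest_path_length(g, "a", "a") == 0
        assert shortest_path_length(g, "a", "c") == 2

    def test_disconnected_is_absent(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        assert shortest_path_length(g, "a", "b") is None

    def test_unknown_node_is_hard_error(self):
        with pytest.raises(KeyError):
            shortest_path_length(nx.path_graph(["a", "b"]), "a", "zzz")

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            n = int(rng.integers(2, 31))
            p = rng.uniform(0.05, 0.4)
            adj = np.triu((rng.random((n, n)) < p).astype(float), k=1)
            adj = adj + adj.T
            g = nx.from_numpy_array(adj)
            dist = floyd_warshall(adj, directed=False, unweighted=True)
            a, b = int(rng.integers(0, n)), int(rng.integers(0, n))
            expected = None if np.isinf(dist[a, b]) else int(dist[a, b])
            assert shortest_path_length(g, a, b) == expected


class TestDirectTargets:
    def test_mapped_and_unmapped_genes(self):
        calls = [call("G1")]
        dm = drug_map([("D1", "drugA", "G1"), ("D2", "drugB", "G9")])
        anns = map_direct_targets(calls, dm)
        assert [(a.gene_id, a.drug_id, a.path_length, a.anchor_target) for a in anns] == [
            ("G1", "D1", 0, "G1")
        ]

    def test_equals_nested_loop_join(self):
        calls = [call(g, snp=f"rs{g}") for g in ("G1", "G2", "G3")]
        rows = [
            ("D1", "a", "G1"), ("D1", "a", "G2"), ("D2", "b", "G2"),
            ("D2", "b", "G9"), ("D3", "c", "G3"),
        ]
        anns = map_direct_targets(calls, drug_map(rows))
        expected = {
            (d, g) for d, _, g in rows for c in calls if c.gene_id == g
        }
        assert {(a.drug_id, a.gene_id) for a in anns} == expected


class TestPpiIndirect:
    def test_empty_graph(self):
        assert ppi_indirect_targets([call("G1")], drug_map([("D1", "a", "G1")]), nx.Graph()) == []

    def test_star_graph_leaf_annotated(self):
        g = nx.star_graph(["HUB", "L1", "L2"])
        calls = [call("HUB"), call("L1", snp="rs2")]
        anns = ppi_indirect_targets(calls, drug_map([("D1", "a", "HUB")]), g)
        assert [(a.gene_id, a.path_length, a.anchor_target) for a in anns] == [("L1", 1, "HUB")]

    def test_direct_genes_not_reannotated(self):
        g = nx.path_graph(["G1", "G2"])
        calls = [call("G1"), call("G2", snp="rs2")]
        dm = drug_map([("D1", "a", "G1"), ("D1", "a", "G2")])
        assert ppi_indirect_targets(calls, dm, g) == []

    def test_matches_adjacency_oracle_on_random_graphs(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(30)]
        for _ in range(20):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(0, 2**31)))
            g = nx.relabel_nodes(g, dict(enumerate(genes)))
            tarsnp_genes = sorted(rng.choice(genes, size=8, replace=False))
            drug_genes = sorted(rng.choice(genes, size=5, replace=False))
            calls = [call(x, snp=f"rs{x}") for x in tarsnp_genes]
            dm = drug_map([("D1", "a", x) for x in drug_genes])
            anns = ppi_indirect_targets(calls, dm, g)
            directs = set(drug_genes) & set(tarsnp_genes)
            expected = {
                x
                for x in tarsnp_genes
                if x not in directs and any(g.has_edge(x, t) for t in directs)
            }
            assert {a.gene_id for a in anns} == expected
            assert all(a.path_length == 1 for a in anns)

    def test_partition_direct_and_ppin_disjoint_per_drug(self):
        g = nx.path_graph(["G1", "G2", "G3"])
        calls = [call(x, snp=f"rs{x}") for x in ("G1", "G2", "G3")]
        dm = drug_map([("D1", "a", "G1"), ("D1", "a", "G3")])
        direct = {(a.gene_id, a.drug_id) for a in map_direct_targets(calls, dm)}
        ppin = {(a.gene_id, a.drug_id) for a in ppi_indirect_targets(calls, dm, g)}
        assert direct & ppin == set()


def pathway(pid, members, edges, pclass="nonmetabolic"):
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(edges)
    return PathwayGraph(pathway_id=pid, pathway_class=pclass,
                        members=frozenset(members), graph=g)


class TestPathwayIndirect:
    def test_direct_edge_gives_distance_one(self):
        pw = pathway("P1", ["T", "G"], [("T", "G")])
        anns = pathway_indirect_targets(
            [call("T"), call("G", snp="rs2")], drug_map([("D1", "a", "T")]), [pw]
        )
        assert [(a.gene_id, a.path_length, a.pathway_id) for a in anns] == [("G", 1, "P1")]

    def test_chain_distance_three(self):
        members = ["T", "x", "y", "G"]
        pw = pathway("P1", members, [("T", "x"), ("x", "y"), ("y", "G")])
        anns = pathway_indirect_targets(
            [call("T"), call("G", snp="rs2")], drug_map([("D1", "a", "T")]), [pw]
        )
        assert anns[0].path_length == 3

    def test_disconnected_member_has_absent_distance(self):
        pw = pathway("P1", ["T", "G"], [])
        anns = pathway_indirect_targets(
            [call("T"), call("G", snp="rs2")], drug_map([("D1", "a", "T")]), [pw]
        )
        assert anns[0].path_length is None

    def test_pathway_without_direct_target_yields_nothing(self):
        pw = pathway("P1", ["G", "x"], [("G", "x")])
        anns = pathway_indirect_targets(
            [call("G")], drug_map([("D1", "a", "T_not_member")]), [pw]
        )
        assert anns == []

    def test_minimum_distance_across_pathways_ties_by_id(self):
        far = pathway("P1", ["T", "x", "G"], [("T", "x"), ("x", "G")])
        near = pathway("P2", ["T", "G"], [("T", "G")])
        anns = pathway_indirect_targets(
            [call("T"), call("G", snp="rs2")], drug_map([("D1", "a", "T")]), [far, near]
        )
        assert [(a.path_length, a.pathway_id) for a in anns] == [(1, "P2")]

    def test_clique_assumption_when_no_edge_table(self, tmp_path):
        members = tmp_path / "members.tsv"
        members.write_text(
            "pathway_id\tpathway_class\tgene_id\n"
            "P1\tmetabolic\tT\nP1\tmetabolic\tG\nP1\tmetabolic\tx\n"
        )
        (pw,) = load_pathways(str(members), edges_path=None, clique_if_no_edges=True)
        assert shortest_path_length(pw.graph, "G", "x") == 1
        anns = pathway_indirect_targets(
            [call("T"), call("G", snp="rs2")], drug_map([("D1", "a", "T")]), [pw]
        )
        assert anns[0].path_length == 1

    def test_edges_outside_membership_are_rejected(self):
        with pytest.raises(ValueError):
            pathway("P1", ["a", "b"], [("a", "z")])


class TestResponseDirection:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            (EffectClass.COMPLETE_GAIN, "sensitivity"),
            (EffectClass.PARTIAL_GAIN, "sensitivity"),
            (EffectClass.COMPLETE_LOSS, "resistance"),
            (EffectClass.PARTIAL_LOSS, "resistance"),
        ],
    )
    def test_four_entry_table(self, cls, expected):
        assert predict_response_direction(cls) == expected

    def test_no_effect_is_an_error(self):
        with pytest.raises(ValueError):
            predict_response_direction(EffectClass.NO_EFFECT)
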