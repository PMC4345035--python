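"""Bounded-distance indication inference and path ranking."""

import random

import pytest

from conftest import chain_rows, floyd_warshall, make_row, random_graph_rows
from cpn.model import UsageError
from cpn.network import graph_from_rows
from cpn.repurposing import degree_profile, infer_indications


def planted_distance_graph():
    """One drug with a disease planted at each exact distance 1..5."""
    rows = [make_row("QueryDrug", "drug", "Disease d1", "disease")]
    for d in range(2, 6):
        chain = [("QueryDrug", "drug")]
        chain += [(f"G{d}_{i}", "gene") for i in range(1, d)]
        chain += [(f"Disease d{d}", "disease")]
        rows += chain_rows(chain)
    return graph_from_rows(rows)


class TestRadiusSemantics:
    def test_only_diseases_within_radius_returned(self):
        cpn = planted_distance_graph()
        cands = infer_indications(cpn, "QueryDrug", radius=3)
        got = {cpn.graph.nodes[c.disease]["name"]: c.distance for c in cands}
        assert got == {"Disease d1": 1, "Disease d2": 2, "Disease d3": 3}
        assert max(c.distance for c in cands) == 3

    def test_default_radius_is_three_edges(self):
        cands = infer_indications(planted_distance_graph(), "QueryDrug")
        assert max(c.distance for c in cands) == 3

    def test_completeness_against_distance_oracle(self):
        rng = random.Random(99)
        rows, _, keys, edges = random_graph_rows(rng, 40, 70)
        cpn = graph_from_rows(rows)
        drugs = [n for n, d in cpn.graph.nodes(data=True)
                 if d["ctype"] == "drug"]
        drug = sorted(drugs)[0]
        idx = keys.index(drug)
        dist = floyd_warshall(40, edges)
        expected = {keys[i] for i in range(40)
                    if 1 <= dist[idx][i] <= 3
                    and cpn.graph.nodes.get(keys[i], {}).get("ctype") == "disease"}
        cands = infer_indications(cpn, drug, radius=3)
        assert {c.disease for c in cands} == expected


class TestCaseStudyChains:
    def test_capecitabine_style_shortest_path_through_gene(self):
        rows = chain_rows([("Capecitabine", "drug"), ("CYP1A1", "gene"),
                           ("Urinary Bladder Neoplasms", "disease")])
        rows += chain_rows([("Capecitabine", "drug"), ("DPYD", "gene"),
                            ("C18orf56", "gene"),
                            ("Urinary Bladder Neoplasms", "disease")])
        cands = infer_indications(graph_from_rows(rows), "Capecitabine")
        target = next(c for c in cands
                      if "urinary bladder" in c.disease)
        assert target.distance == 2
        assert target.shortest.nodes == ("drug:capecitabine", "gene:cyp1a1",
                                         "disease:urinary bladder neoplasms")
        assert len(target.paths) >= 2  # indirect path also enumerated

    def test_paclitaxel_style_gene_and_snp_routes(self):
        rows = [make_row("Paclitaxel", "drug", "MTHFR", "gene"),
                make_row("Paclitaxel", "drug", "rs1801133", "variant"),
                make_row("MTHFR", "gene", "Alzheimer Disease", "disease"),
                make_row("rs1801133", "variant", "Alzheimer Disease",
                         "disease")]
        cands = infer_indications(graph_from_rows(rows), "Paclitaxel")
        assert len(cands) == 1
        c = cands[0]
        assert c.distance == 2 and len(c.paths) == 2
        middles = {p.nodes[1] for p in c.paths}
        assert middles == {"gene:mthfr", "variant:rs1801133"}


class TestRankingAndNovelty:
    def weighted_graph(self):
        rows = [make_row("D", "drug", "G1", "gene"),
                make_row("G1", "gene", "Disease heavy", "disease"),
                make_row("D", "drug", "G2", "gene"),
                make_row("G2", "gene", "Disease light", "disease")]
        cpn = graph_from_rows(rows)
        for node, w in (("gene:g1", 4), ("disease:disease heavy", 3),
                        ("gene:g2", 1), ("disease:disease light", 1),
                        ("drug:d", 1)):
            cpn.graph.nodes[node]["weight"] = w
        return cpn

    def test_equal_length_breaks_tie_on_weight_sum(self):
        cands = infer_indications(self.weighted_graph(), "D")
        assert [c.disease for c in cands] == ["disease:disease heavy",
                                              "disease:disease light"]
        assert cands[0].shortest.weight_sum > cands[1].shortest.weight_sum

    def test_vip_count_breaks_remaining_ties(self):
        cpn = self.weighted_graph()
        for n in cpn.graph.nodes:
            cpn.graph.nodes[n]["weight"] = 1
        cpn.graph.edges["drug:d", "gene:g2"]["vip"] = True
        cands = infer_indications(cpn, "D")
        assert cands[0].disease == "disease:disease light"
        assert cands[0].shortest.vip_count == 1

    def test_ranking_is_deterministic_lexicographic_fallback(self):
        rows = [make_row("D", "drug", "G", "gene"),
                make_row("G", "gene", "B disease", "disease"),
                make_row("G", "gene", "A disease", "disease")]
        cands = infer_indications(graph_from_rows(rows), "D")
        assert [c.disease for c in cands] == ["disease:a disease",
                                              "disease:b disease"]

    def test_novelty_flag_against_known_indications(self):
        rows = [make_row("D", "drug", "G", "gene"),
                make_row("G", "gene", "Known disease", "disease"),
                make_row("G", "gene", "New disease", "disease")]
        cands = infer_indications(graph_from_rows(rows), "D",
                                  known={"disease:known disease"})
        by_name = {c.disease: c.novel for c in cands}
        assert by_name == {"disease:known disease": False,
                           "disease:new disease": True}

    def test_non_drug_query_is_a_usage_error(self):
        cpn = planted_distance_graph()
        with pytest.raises(UsageError, match="expected a drug"):
            infer_indications(cpn, "Disease d1")


class TestDegreeProfile:
    def test_star_graph_counts(self):
        rows = [make_row("hub", "drug", f"G{i}", "gene") for i in range(6)]
        profile = degree_profile(graph_from_rows(rows), "hub", 2)
        assert profile == {1: (6, 0), 2: (0, 0)}

    def test_layered_graph_matches_planted_counts(self):
        cpn = planted_distance_graph()
        profile = degree_profile(cpn, "QueryDrug", 3)
        # layer 1: Disease d1 + 4 chain genes; diseases at exact distances
        assert profile[1] == (5, 1)
        assert profile[2][1] == 1 and profile[3][1] == 1

    def test_counts_partition_reachable_nodes(self):
        rng = random.Random(5)
        rows, _, keys, edges = random_graph_rows(rng, 25, 40)
        cpn = graph_from_rows(rows)
        center = sorted(cpn.graph.nodes)[0]
        profile = degree_profile(cpn, center, 4)
        import networkx as nx

        reach = nx.single_source_shortest_path_length(cpn.graph, center,
                                                      cutoff=4)
        assert sum(t for t, _ in profile.values()) == len(reach) - 1
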