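"""Degree-limited seed expansion and the GWAS co-occurrence filter."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import chain_rows, floyd_warshall, make_row, random_graph_rows
from cpn.model import IntegrationError, SeedList, concept_key
from cpn.expansion import (
    apply_gwas_cooccurrence_filter,
    build_pair_graph,
    expand_from_seeds,
)


def seed_list(*terms):
    return SeedList.from_terms(terms)


class TestWorkedExample:
    def test_example_chain_degrees_and_weights(self, worked_example):
        from cpn import sources as src

        rel, seeds = worked_example
        rows = src.read_pharmgkb_relationships(rel).rows
        result = expand_from_seeds(rows, src.read_seed_list(seeds))
        expected = {
            "disease:urinary bladder neoplasms": (0, 5),
            "variant:rs762551": (1, 4),
            "disease:arthritis, rheumatoid": (2, 3),
            "gene:cyp1a2": (3, 2),
            "drug:olanzapine": (4, 1),
        }
        got = {k: (r.degree, r.weight) for k, r in result.degrees.items()}
        assert got == expected


class TestExpansion:
    def test_depth_cap_on_long_chain(self):
        # 10-node chain: only 4 non-seed concepts survive the cap
        chain = [(f"N{i}", "gene") for i in range(1, 10)]
        rows = chain_rows([("seed disease", "disease")] + chain)
        result = expand_from_seeds(rows, seed_list("seed disease"), max_degree=4)
        non_seed = [k for k, r in result.degrees.items() if r.degree > 0]
        assert len(non_seed) == 4
        assert max(r.degree for r in result.degrees.values()) == 4

    def test_unresolved_seed_logged_not_fatal(self):
        rows = [make_row("DiseaseA", "disease", "G1", "gene")]
        result = expand_from_seeds(rows, seed_list("DiseaseA", "no such term"))
        assert result.unresolved_seeds == ["no such term"]
        assert len(result.concepts) == 2

    def test_self_loops_dropped(self):
        rows = [make_row("rs1", "variant", "rs1", "variant"),
                make_row("DiseaseA", "disease", "rs1", "variant")]
        result = expand_from_seeds(rows, seed_list("DiseaseA"))
        assert result.dropped_self_loops == 1
        assert len(result.associations) == 1

    def test_every_retained_association_connects_retained_concepts(self):
        rows = chain_rows([("S", "disease"), ("a", "gene"), ("b", "gene"),
                           ("c", "gene"), ("d", "gene"), ("e", "gene")])
        result = expand_from_seeds(rows, seed_list("S"), max_degree=4)
        keys = result.keys
        assert concept_key("gene", "e") not in keys
        for assoc in result.associations:
            assert assoc.a.key in keys and assoc.b.key in keys

    def test_duplicate_pairs_merge_pmids_and_sources(self):
        rows = [make_row("D", "disease", "G", "gene", pmids=("1",)),
                make_row("G", "gene", "D", "disease", pmids=("2",),
                         source="gwas")]
        result = expand_from_seeds(rows, seed_list("D"))
        assert len(result.associations) == 1
        assert result.associations[0].pmids == {"1", "2"}
        assert result.associations[0].sources == {"pharmgkb", "gwas"}

    def test_conflicting_ctype_raises_integration_error(self):
        rows = [make_row("D", "disease", "X", "gene"),
                make_row("D", "disease", "X", "drug")]
        with pytest.raises(IntegrationError, match="'X'"):
            build_pair_graph(rows)


class TestOracleEquivalence:
    """Expansion degrees equal brute-force all-pairs shortest paths."""

    def assert_matches_oracle(self, rng, n_nodes, n_edges, n_seeds,
                              max_degree=4):
        rows, seeds, keys, edges = random_graph_rows(rng, n_nodes, n_edges,
                                                     n_seeds)
        result = expand_from_seeds(rows, seeds, max_degree=max_degree)
        dist = floyd_warshall(n_nodes, edges)
        incident = {i for e in edges for i in e}
        expected = {}
        for i, key in enumerate(keys):
            if i not in incident:
                continue  # never appears in the association table
            d = min(dist[s][i] for s in range(n_seeds))
            if d <= max_degree:
                expected[key] = d
        got = {k: r.degree for k, r in result.degrees.items()}
        assert got == expected

    def test_exhaustive_small_graphs(self):
        rng = random.Random(202)
        for trial in range(200):
            n = rng.randint(2, 12)
            m = rng.randint(1, n * (n - 1) // 2)
            self.assert_matches_oracle(rng, n, m, n_seeds=rng.randint(1, 2))

    def test_random_medium_graphs(self):
        rng = random.Random(303)
        for trial in range(100):
            n = rng.randint(13, 60)
            m = rng.randint(n // 2, 2 * n)
            self.assert_matches_oracle(rng, n, m, n_seeds=rng.randint(1, 3))


class TestProperties:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(3, 25))
    def test_weight_plus_degree_is_five_and_order_invariance(self, seed, n):
        rng = random.Random(seed)
        rows, seeds, keys, edges = random_graph_rows(rng, n, max(1, 2 * n // 3))
        result = expand_from_seeds(rows, seeds)
        for rec in result.degrees.values():
            assert rec.weight + rec.degree == 5

        # invariance to row order and to swapping entity1/entity2
        swapped = [make_row(r.entity2_name, r.entity2_type, r.entity1_name,
                            r.entity1_type, pmids=r.pmids, source=r.source)
                   for r in reversed(rows)]
        result2 = expand_from_seeds(swapped, seeds)
        assert {k: r.degree for k, r in result.degrees.items()} == \
            {k: r.degree for k, r in result2.degrees.items()}


class TestGwasCooccurrence:
    def rows(self):
        return [make_row("trait", "disease", "KNOWN", "gene", source="gwas"),
                make_row("trait2", "disease", "NOVEL", "gene", source="gwas")]

    def test_any_mode_keeps_rows_with_one_known_endpoint(self):
        known = {concept_key("gene", "KNOWN")}
        kept = apply_gwas_cooccurrence_filter(self.rows(), known, mode="any")
        assert [r.entity2_name for r in kept] == ["KNOWN"]

    def test_both_mode_requires_both_endpoints(self):
        known = {concept_key("gene", "KNOWN")}
        assert apply_gwas_cooccurrence_filter(self.rows(), known,
                                              mode="both") == []
        known.add(concept_key("disease", "trait"))
        kept = apply_gwas_cooccurrence_filter(self.rows(), known, mode="both")
        assert len(kept) == 1

    def test_empty_known_set_annihilates(self):
        assert apply_gwas_cooccurrence_filter(self.rows(), set()) == []
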