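"""Shared fixtures: row factories, random graphs, and a brute-force
shortest-path oracle kept independent of the library's BFS."""

from __future__ import annotations

import random

import pytest

from cpn.model import CONCEPT_TYPES, RawAssociationRow, SeedList, concept_key
from cpn.sources import packaged_example


def make_row(name1, type1, name2, type2, pmids=(), source="pharmgkb",
             id1=None, id2=None):
    return RawAssociationRow(
        entity1_id=id1 or name1, entity1_name=name1, entity1_type=type1,
        entity2_id=id2 or name2, entity2_name=name2, entity2_type=type2,
        pmids=tuple(pmids), source=source)


def chain_rows(names_types, source="pharmgkb"):
    """Rows linking consecutive (name, ctype) entries of a chain."""
    rows = []
    for (n1, t1), (n2, t2) in zip(names_types, names_types[1:]):
        rows.append(make_row(n1, t1, n2, t2))
    return rows


def floyd_warshall(n: int, edges: set[tuple[int, int]]) -> list[list[float]]:
    """All-pairs shortest paths by the textbook triple loop (the oracle)."""
    inf = float("inf")
    d = [[inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0
    for i, j in edges:
        if i != j:
            d[i][j] = d[j][i] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            row_k = d[k]
            for j in range(n):
                if dik + row_k[j] < d[i][j]:
                    d[i][j] = dik + row_k[j]
    return d


def random_graph_rows(rng: random.Random, n_nodes: int, n_edges: int,
                      n_seeds: int = 1):
    """A random typed pair table plus the matching oracle inputs.

    Returns (rows, seed_list, node_names, edges) where ``edges`` are
    index pairs usable with :func:`floyd_warshall`.  Node 0..n_seeds-1
    are diseases used as seeds.
    """
    names, ctypes = [], []
    for i in range(n_nodes):
        ctype = "disease" if i < n_seeds else CONCEPT_TYPES[i % len(CONCEPT_TYPES)]
        names.append(f"Node {i}" if ctype != "variant" else f"rs{i}")
        ctypes.append(ctype)
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.randrange(n_nodes), rng.randrange(n_nodes)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    rows = [make_row(names[i], ctypes[i], names[j], ctypes[j])
            for i, j in sorted(edges)]
    rng.shuffle(rows)
    seeds = SeedList.from_terms(names[:n_seeds])
    keys = [concept_key(ctypes[i], names[i]) for i in range(n_nodes)]
    return rows, seeds, keys, edges


@pytest.fixture(scope="session")
def worked_example():
    """(relationships path, seeds path) of the packaged worked example."""
    return packaged_example()


@pytest.fixture()
def bundle(tmp_path):
    """A default synthetic bundle generated fresh into tmp_path."""
    from cpn.synth import GeneratorConfig, generate_bundle

    paths, truth = generate_bundle(GeneratorConfig(rng_seed=11),
                                   tmp_path / "bundle")
    return paths, truth


def pipeline_config_for(paths, truth, outdir):
    from cpn.pipeline import PipelineConfig

    return PipelineConfig(
        relationships=str(paths["relationships"]), seeds=str(paths["seeds"]),
        entities=str(paths["entities"]), gwas=str(paths["gwas"]),
        fda=str(paths["fda"]), predications=str(paths["predications"]),
        lexicon=str(paths["lexicon"]), overrides=str(paths["overrides"]),
        known_indications=str(paths["known_indications"]),
        vip_pairs=str(paths["vip_pairs"]), outdir=str(outdir),
        query_drugs=tuple(truth.query_drugs))
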