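"""Seed-based iterative association extraction with degree weights.

Starting from the cancer seed terms, the association table is explored
breadth-first over the undirected concept-pair graph.  A concept's
degree is its minimal edge distance from any seed; concepts up to
``max_degree`` (default 4) are retained and scored ``weight = 5 - degree``
(first-degree concepts score 4, fourth-degree concepts score 1),
encoding the assumption that seed-proximal concepts are more strongly
cancer-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    Association,
    Concept,
    DegreeRecord,
    IntegrationError,
    RawAssociationRow,
    SeedList,
    concept_key,
    norm_name,
)

log = logging.getLogger(__name__)


@dataclass
class ExpansionResult:
    concepts: dict[str, Concept]
    associations: list[Association]
    degrees: dict[str, DegreeRecord]
    unresolved_seeds: list[str] = field(default_factory=list)
    dropped_self_loops: int = 0

    @property
    def keys(self) -> set[str]:
        return set(self.concepts)


def build_pair_graph(rows: list[RawAssociationRow]) -> tuple[nx.Graph, int]:
    """Build the undirected concept graph from association rows.

    Duplicate unordered pairs are merged (PMIDs and sources unioned);
    self-loops are dropped and counted.  A concept key observed with two
    different concept types raises :class:`IntegrationError`.
    """
    graph = nx.Graph()
    conflicts: list[str] = []
    ctype_by_name: dict[str, str] = {}
    self_loops = 0

    def add_node(ctype: str, name: str) -> str:
        key = concept_key(ctype, name)
        prev = ctype_by_name.setdefault(norm_name(name), ctype)
        if prev != ctype:
            conflicts.append(f"{name!r}: {prev} vs {ctype}")
        if key not in graph.nodes:
            graph.add_node(key, name=name.strip(), ctype=ctype)
        return key

    for row in rows:
        k1 = add_node(row.entity1_type, row.entity1_name)
        k2 = add_node(row.entity2_type, row.entity2_name)
        if k1 == k2:
            self_loops += 1
            continue
        if graph.has_edge(k1, k2):
            data = graph.edges[k1, k2]
            data["pmids"].update(row.pmids)
            data["sources"].add(row.source)
        else:
            graph.add_edge(k1, k2, pmids=set(row.pmids), sources={row.source})
    if conflicts:
        raise IntegrationError(
            "conflicting concept types: " + "; ".join(sorted(set(conflicts))))
    return graph, self_loops


def resolve_seeds(graph: nx.Graph, seeds: SeedList
                  ) -> tuple[list[str], list[str]]:
    """Match seed terms to graph nodes by name, case-insensitively."""
    by_name: dict[str, list[str]] = {}
    for key, data in graph.nodes(data=True):
        by_name.setdefault(norm_name(data["name"]), []).append(key)
    resolved, unresolved = [], []
    for term in seeds.terms:
        hits = by_name.get(norm_name(term))
        if hits:
            resolved.extend(sorted(hits))
        else:
            unresolved.append(term)
    return resolved, unresolved


def _multi_source_bfs(graph: nx.Graph, seed_keys: list[str],
                      cutoff: int) -> dict[str, int]:
    """Minimal edge distance from the joint seed set, capped at ``cutoff``.

    This is the iterative seed search: first-degree concepts are
    direct seed neighbours, second-degree concepts are their neighbours,
    and so on until the cutoff degree has been extracted.
    """
    from collections import deque

    dist = {k: 0 for k in seed_keys}
    queue = deque(seed_keys)
    while queue:
        node = queue.popleft()
        if dist[node] == cutoff:
            continue
        for nb in graph.adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def expand_from_seeds(associations: list[RawAssociationRow], seeds: SeedList,
                      max_degree: int = 4) -> ExpansionResult:
    """Retain all concepts within ``max_degree`` edges of any seed.

    Returns the retained concepts, the associations among them (merged
    unordered pairs), and one :class:`DegreeRecord` per concept whose
    degree is the minimum distance over all seeds and discovery paths.
    Seeds that match no concept are logged and reported, not fatal.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    graph, self_loops = build_pair_graph(associations)
    seed_keys, unresolved = resolve_seeds(graph, seeds)
    for term in unresolved:
        log.warning("seed %r matches no concept in the association table", term)

    distances = _multi_source_bfs(graph, seed_keys, cutoff=max_degree)

    concepts: dict[str, Concept] = {}
    degrees: dict[str, DegreeRecord] = {}
    for key, dist in distances.items():
        data = graph.nodes[key]
        concepts[key] = Concept(key=key, name=data["name"],
                                ctype=data["ctype"], sources=frozenset())
        degrees[key] = DegreeRecord.for_degree(key, dist)

    merged: list[Association] = []
    node_sources: dict[str, set[str]] = {k: set() for k in concepts}
    for k1, k2, data in graph.edges(data=True):
        if k1 in concepts and k2 in concepts:
            a, b = sorted((k1, k2))
            merged.append(Association(a=concepts[a], b=concepts[b],
                                      sources=set(data["sources"]),
                                      pmids=set(data["pmids"])))
            node_sources[a] |= data["sources"]
            node_sources[b] |= data["sources"]
    for key, srcs in node_sources.items():
        c = concepts[key]
        concepts[key] = Concept(key, c.name, c.ctype, frozenset(srcs))
    merged.sort(key=lambda assoc: assoc.key)
    return ExpansionResult(concepts=concepts, associations=merged,
                           degrees=degrees, unresolved_seeds=unresolved,
                           dropped_self_loops=self_loops)


def apply_gwas_cooccurrence_filter(gwas_rows: list[RawAssociationRow],
                                   pharmgkb_keys: set[str],
                                   mode: str = "any"
                                   ) -> list[RawAssociationRow]:
    """Keep GWAS rows co-occurring with the PharmGKB expansion.

    ``mode='any'`` (default) keeps a row when at least one endpoint
    resolves to a known PharmGKB concept key; ``mode='both'`` requires
    both endpoints.
    """
    if mode not in ("any", "both"):
        raise ValueError(f"unknown co-occurrence mode {mode!r}")
    test = any if mode == "any" else all
    out = []
    for row in gwas_rows:
        k1 = concept_key(row.entity1_type, row.entity1_name)
        k2 = concept_key(row.entity2_type, row.entity2_name)
        if test(k in pharmgkb_keys for k in (k1, k2)):
            out.append(row)
    return out
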