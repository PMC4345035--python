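"""Assembly, validation and export of the cancer PGx network (CPN).

Nodes are merged across resources by a shared identity: the normalized
vocabulary code when one exists (``RxNorm:56946``), otherwise the typed,
case-folded name (``drug:paclitaxel``).  Edges are merged by unordered
pair; each edge's pair type is validated against a per-source matrix of
allowed association types (strict mode raises, permissive mode warns).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    Association,
    Concept,
    ConceptLookupError,
    DegreeRecord,
    FormatError,
    IntegrationError,
    NormalizedConcept,
    RawAssociationRow,
    concept_key,
    pair_type,
)
from .expansion import ExpansionResult

log = logging.getLogger(__name__)

#: allowed association types per resource
DEFAULT_PAIR_TYPE_MATRIX: dict[str, frozenset[str]] = {
    "pharmgkb": frozenset({"disease-gene", "disease-haplotype", "disease-snp",
                           "drug-gene", "drug-haplotype", "drug-snp",
                           "drug-drug", "gene-gene"}),
    "gwas": frozenset({"disease-gene", "disease-snp", "gene-snp"}),
    "fda": frozenset({"drug-gene"}),
}

_SET_ATTRS = ("sources", "pmids", "predicates")


@dataclass
class CPNGraph:
    """The assembled network: an attributed undirected networkx graph."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def require_node(self, key: str) -> str:
        """Resolve a node by key or (case-insensitive) name."""
        if key in self.graph:
            return key
        from .model import norm_name

        wanted = norm_name(key)
        hits = [n for n, d in self.graph.nodes(data=True)
                if norm_name(d.get("name", "")) == wanted or n == wanted]
        if len(hits) == 1:
            return hits[0]
        near = sorted(n for n, d in self.graph.nodes(data=True)
                      if wanted.split(":")[-1] in norm_name(d.get("name", "")))
        raise ConceptLookupError(
            f"concept {key!r} not in graph"
            + (f"; near misses: {near[:5]}" if near else ""))

    def stats(self) -> dict:
        nodes_by_ctype: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            nodes_by_ctype[d["ctype"]] = nodes_by_ctype.get(d["ctype"], 0) + 1
        edges_by_type: dict[str, int] = {}
        edges_by_source: dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            pt = d["pair_type"]
            edges_by_type[pt] = edges_by_type.get(pt, 0) + 1
            for s in d["sources"]:
                edges_by_source[s] = edges_by_source.get(s, 0) + 1
        return {"n_nodes": self.n_nodes, "n_edges": self.n_edges,
                "nodes_by_ctype": dict(sorted(nodes_by_ctype.items())),
                "edges_by_pair_type": dict(sorted(edges_by_type.items())),
                "edges_by_source": dict(sorted(edges_by_source.items()))}


def merge_key(concept: Concept,
              norms: dict[str, NormalizedConcept] | None) -> str:
    """Cross-resource node identity: vocabulary code if normalized."""
    nc = (norms or {}).get(concept.key)
    if nc is not None and nc.code is not None and nc.vocabulary != "none":
        return f"{nc.vocabulary}:{nc.code}"
    return concept.key


def _add_concept(graph: nx.Graph, concept: Concept,
                 norms, degrees: dict[str, DegreeRecord] | None) -> str:
    node = merge_key(concept, norms)
    nc = (norms or {}).get(concept.key)
    rec = (degrees or {}).get(concept.key)
    if node in graph:
        data = graph.nodes[node]
        if data["ctype"] != concept.ctype:
            raise IntegrationError(
                f"node {node}: ctype conflict {data['ctype']} vs {concept.ctype}")
        data["sources"] |= set(concept.sources)
        if rec is not None and (data.get("degree") is None
                                or rec.degree < data["degree"]):
            data["degree"], data["weight"] = rec.degree, rec.weight
    else:
        graph.add_node(node, name=concept.name, ctype=concept.ctype,
                       sources=set(concept.sources),
                       code=nc.code if nc else None,
                       vocabulary=nc.vocabulary if nc else None,
                       method=nc.method if nc else None,
                       degree=rec.degree if rec else None,
                       weight=rec.weight if rec else None)
    return node


def _add_edge(graph: nx.Graph, n1: str, n2: str, sources, pmids,
              predicates=()) -> None:
    if n1 == n2:
        return  # self-loop after merging; drop
    if graph.has_edge(n1, n2):
        d = graph.edges[n1, n2]
        d["sources"] |= set(sources)
        d["pmids"] |= set(pmids)
        d["predicates"] |= set(predicates)
    else:
        graph.add_edge(n1, n2,
                       pair_type=pair_type(graph.nodes[n1]["ctype"],
                                           graph.nodes[n2]["ctype"]),
                       sources=set(sources), pmids=set(pmids),
                       predicates=set(predicates), vip=False)


def validate_pair_types(graph: nx.Graph,
                        matrix: dict[str, frozenset[str]],
                        strict: bool = True) -> list[str]:
    """Check every edge's pair type against the per-source matrix."""
    violations = []
    for n1, n2, d in graph.edges(data=True):
        for src in sorted(d["sources"]):
            allowed = matrix.get(src, frozenset())
            if d["pair_type"] not in allowed:
                violations.append(
                    f"{n1} -- {n2}: pair type {d['pair_type']!r} not allowed "
                    f"for source {src!r}")
    if violations:
        if strict:
            raise IntegrationError("pair-type violations:\n"
                                   + "\n".join(violations))
        for v in violations:
            log.warning("pair-type violation (permissive): %s", v)
    return violations


def build_cpn(pharmgkb: ExpansionResult,
              gwas_rows: list[RawAssociationRow] = (),
              fda_rows: list[RawAssociationRow] = (),
              norms: dict[str, NormalizedConcept] | None = None,
              evidence=None,
              matrix: dict[str, frozenset[str]] = DEFAULT_PAIR_TYPE_MATRIX,
              strict: bool = True,
              vip_pairs: set[tuple[str, str]] | None = None) -> CPNGraph:
    """Assemble the CPN from the three resources' association sets.

    ``pharmgkb`` is the degree-bounded expansion output; ``gwas_rows``
    must already have passed the co-occurrence filter.  ``evidence`` is
    the attachment list produced by :func:`cpn.evidence.attach_evidence`,
    keyed by pre-merge concept keys.
    """
    graph = nx.Graph()
    key_map: dict[str, str] = {}  # pre-merge concept key -> node id

    for key, concept in sorted(pharmgkb.concepts.items()):
        key_map[key] = _add_concept(graph, concept, norms, pharmgkb.degrees)
    for assoc in pharmgkb.associations:
        _add_edge(graph, key_map[assoc.a.key], key_map[assoc.b.key],
                  assoc.sources, assoc.pmids, assoc.predicates)

    for row in list(gwas_rows) + list(fda_rows):
        c1 = Concept.from_name(row.entity1_type, row.entity1_name,
                               sources=(row.source,))
        c2 = Concept.from_name(row.entity2_type, row.entity2_name,
                               sources=(row.source,))
        n1 = key_map.setdefault(c1.key,
                                _add_concept(graph, c1, norms, pharmgkb.degrees))
        n2 = key_map.setdefault(c2.key,
                                _add_concept(graph, c2, norms, pharmgkb.degrees))
        graph.nodes[n1]["sources"].add(row.source)
        graph.nodes[n2]["sources"].add(row.source)
        _add_edge(graph, n1, n2, {row.source}, row.pmids)

    for att in evidence or []:
        k1, k2 = (key_map.get(att.pair[0]), key_map.get(att.pair[1]))
        if k1 is None or k2 is None or not graph.has_edge(k1, k2):
            continue
        d = graph.edges[k1, k2]
        d["pmids"] |= set(att.pmids)
        d["predicates"] |= set(att.predicates)

    for pair in vip_pairs or set():
        k1, k2 = (key_map.get(pair[0], pair[0]), key_map.get(pair[1], pair[1]))
        if graph.has_edge(k1, k2):
            graph.edges[k1, k2]["vip"] = True

    validate_pair_types(graph, matrix, strict=strict)
    return CPNGraph(graph)


def graph_from_rows(rows: list[RawAssociationRow],
                    norms=None, degrees=None) -> CPNGraph:
    """Assemble a CPN directly from association rows (no seed expansion)."""
    graph = nx.Graph()
    for row in rows:
        c1 = Concept.from_name(row.entity1_type, row.entity1_name,
                               sources=(row.source,))
        c2 = Concept.from_name(row.entity2_type, row.entity2_name,
                               sources=(row.source,))
        n1 = _add_concept(graph, c1, norms, degrees)
        n2 = _add_concept(graph, c2, norms, degrees)
        _add_edge(graph, n1, n2, {row.source}, row.pmids)
    return CPNGraph(graph)


def subnetwork(cpn: CPNGraph, center: str, radius: int) -> CPNGraph:
    """Induced subgraph on nodes within ``radius`` edges of ``center``."""
    node = cpn.require_node(center)
    return CPNGraph(nx.ego_graph(cpn.graph, node, radius=radius).copy())


# ---------------------------------------------------------------- export

def _serialize(value):
    if isinstance(value, (set, frozenset)):
        return ";".join(sorted(value))
    return value


def export_graph(cpn: CPNGraph, fmt: str, path) -> None:
    """Write the graph as SIF, GraphML or node/edge attribute TSVs.

    SIF is the attribute-free Cytoscape convenience format; GraphML is
    the canonical attribute-preserving round-trip format; ``tsv`` writes
    ``<path>.nodes.tsv`` and ``<path>.edges.tsv``.
    """
    if fmt == "sif":
        lines = sorted(f"{min(u, v)}\t{d['pair_type']}\t{max(u, v)}"
                       for u, v, d in cpn.graph.edges(data=True))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for n, d in cpn.graph.nodes(data=True):
            g.add_node(n, **{k: _serialize(v) for k, v in d.items()
                             if v is not None})
        for u, v, d in cpn.graph.edges(data=True):
            g.add_edge(u, v, **{k: _serialize(val) for k, val in d.items()
                                if val is not None})
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        base = str(path)
        with open(base + ".nodes.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["key", "name", "ctype", "code", "vocabulary",
                        "method", "degree", "weight", "sources"])
            for n, d in sorted(cpn.graph.nodes(data=True)):
                w.writerow([n, d["name"], d["ctype"], d.get("code") or "",
                            d.get("vocabulary") or "", d.get("method") or "",
                            "" if d.get("degree") is None else d["degree"],
                            "" if d.get("weight") is None else d["weight"],
                            ";".join(sorted(d["sources"]))])
        with open(base + ".edges.tsv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["key1", "key2", "pair_type", "sources", "pmids",
                        "predicates", "vip"])
            for u, v, d in sorted(cpn.graph.edges(data=True),
                                  key=lambda e: (min(e[0], e[1]),
                                                 max(e[0], e[1]))):
                w.writerow([min(u, v), max(u, v), d["pair_type"],
                            ";".join(sorted(d["sources"])),
                            ";".join(sorted(d["pmids"])),
                            ";".join(sorted(d["predicates"])),
                            int(d.get("vip", False))])
    else:
        raise FormatError(f"unknown export format {fmt!r}")


def load_graphml(path) -> CPNGraph:
    """Re-import a GraphML export, restoring set-valued attributes."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        d = dict(d)
        for attr in _SET_ATTRS:
            if attr in d:
                d[attr] = set(x for x in str(d[attr]).split(";") if x)
        out.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        d = dict(d)
        for attr in _SET_ATTRS:
            if attr in d:
                d[attr] = set(x for x in str(d[attr]).split(";") if x)
        if "vip" in d:
            d["vip"] = bool(d["vip"]) if isinstance(d["vip"], bool) else (
                str(d["vip"]).lower() in ("true", "1"))
        out.add_edge(u, v, **d)
    return CPNGraph(out)
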