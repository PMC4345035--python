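"""Path-based indication inference over the CPN.

Given a query drug, every disease node within a bounded edge distance
(default radius 3, read as edge-distance <= 3) is a repurposing
candidate.  Candidates are ranked by their best supporting path using
the tuple (path length ascending, sum of node weight scores descending,
count of VIP-flagged edges descending), with lexicographic concept keys
as the final tie-break, and flagged novel when the disease is absent
from the drug's known-indication list.
"""

from __future__ import annotations

import csv
import itertools

import networkx as nx

from .model import IndicationCandidate, PathResult, UsageError
from .network import CPNGraph


def _path_result(graph: nx.Graph, nodes: list[str]) -> PathResult:
    weight_sum = sum(graph.nodes[n].get("weight") or 0 for n in nodes)
    vip = sum(1 for u, v in zip(nodes, nodes[1:])
              if graph.edges[u, v].get("vip", False))
    return PathResult(nodes=tuple(nodes), length=len(nodes) - 1,
                      weight_sum=weight_sum, vip_count=vip)


def _path_order(p: PathResult) -> tuple:
    return (p.length, -p.weight_sum, -p.vip_count, p.nodes)


def infer_indications(cpn: CPNGraph, drug: str, radius: int = 3,
                      known: set[str] | None = None,
                      max_paths_per_disease: int = 25,
                      ) -> list[IndicationCandidate]:
    """Rank disease nodes within ``radius`` edges of the query drug.

    For each candidate disease, simple paths of length <= ``radius``
    are enumerated (capped at ``max_paths_per_disease``, best-first by
    the ranking key).  Raises :class:`UsageError` when the query concept
    is not a drug and a lookup error when it is absent.
    """
    if radius < 1:
        raise UsageError("radius must be >= 1")
    node = cpn.require_node(drug)
    graph = cpn.graph
    if graph.nodes[node]["ctype"] != "drug":
        raise UsageError(
            f"query concept {drug!r} has type "
            f"{graph.nodes[node]['ctype']!r}, expected a drug")
    known = set(known or ())

    distances = nx.single_source_shortest_path_length(graph, node,
                                                      cutoff=radius)
    candidates: list[IndicationCandidate] = []
    for target in sorted(distances):
        if target == node or graph.nodes[target]["ctype"] != "disease":
            continue
        paths = [_path_result(graph, p) for p in itertools.islice(
            nx.all_simple_paths(graph, node, target, cutoff=radius),
            50 * max_paths_per_disease)]
        paths.sort(key=_path_order)
        paths = paths[:max_paths_per_disease]
        candidates.append(IndicationCandidate(
            drug=node, disease=target, distance=distances[target],
            paths=paths, shortest=paths[0], novel=target not in known))
    candidates.sort(key=lambda c: c.rank_score)
    return candidates


def degree_profile(cpn: CPNGraph, center: str, max_distance: int
                   ) -> dict[int, tuple[int, int]]:
    """Distinct concept (and disease) counts at each exact distance.

    Mirrors neighbourhood summaries such as "70 concepts directly
    associated, 399 concepts including 110 diseases two nodes away".
    """
    node = cpn.require_node(center)
    distances = nx.single_source_shortest_path_length(cpn.graph, node,
                                                      cutoff=max_distance)
    profile: dict[int, tuple[int, int]] = {
        d: (0, 0) for d in range(1, max_distance + 1)}
    for target, dist in distances.items():
        if dist == 0:
            continue
        total, diseases = profile[dist]
        is_disease = cpn.graph.nodes[target]["ctype"] == "disease"
        profile[dist] = (total + 1, diseases + (1 if is_disease else 0))
    return profile


def load_known_indications(path, cpn: CPNGraph | None = None
                           ) -> dict[str, set[str]]:
    """Read a per-drug known-indication TSV (columns: drug, disease).

    Cells may hold node keys or names; names are resolved against the
    graph when one is supplied.
    """
    known: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            drug = (row.get("drug") or "").strip()
            disease = (row.get("disease") or "").strip()
            if not drug or not disease:
                continue
            if cpn is not None:
                try:
                    drug = cpn.require_node(drug)
                    disease = cpn.require_node(disease)
                except KeyError:
                    continue
            known.setdefault(drug, set()).add(disease)
    return known


def load_vip_pairs(path) -> set[tuple[str, str]]:
    """Read VIP ("very important pharmacogene") edge flags (key1, key2)."""
    pairs: set[tuple[str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            k1, k2 = (row.get("key1") or "").strip(), (row.get("key2") or "").strip()
            if k1 and k2:
                pairs.add((min(k1, k2), max(k1, k2)))
    return pairs


def write_candidates_tsv(candidates: list[IndicationCandidate], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["drug", "disease", "distance", "n_paths",
                    "shortest_path", "weight_sum", "vip_count", "novel"])
        for c in candidates:
            w.writerow([c.drug, c.disease, c.distance, len(c.paths),
                        ">".join(c.shortest.nodes), c.shortest.weight_sum,
                        c.shortest.vip_count, int(c.novel)])
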