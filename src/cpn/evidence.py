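"""Literature-evidence attachment from semantic predications.

PharmGKB rows carry their own PubMed ids, but GWAS and FDA pairs arrive
bare.  This module joins the network's associations against a
SemMedDB-style predication table: a predication decorates an
association when its subject and object names both resolve (exact,
case-insensitive) to the association's two endpoints, in either order.
Evidence only decorates existing edges — it never creates new ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Association, EvidenceAttachment, PredicationRow, norm_name


@dataclass
class EvidenceStats:
    total: int = 0
    with_source_pmids: int = 0
    predication_matched: int = 0
    unmatched: int = 0
    unresolved_predications: int = 0

    @property
    def attached(self) -> int:
        """Associations that ended up with at least one attachment."""
        return self.total - self.unmatched


def build_name_index(concepts, extra_names: dict[str, str] | None = None
                     ) -> dict[str, str]:
    """Lowercased name → concept key, optionally with preferred names.

    ``extra_names`` maps alternative spellings (e.g. normalized
    preferred terms) to concept keys to improve recall.
    """
    if isinstance(concepts, dict):
        concepts = concepts.values()
    index = {norm_name(c.name): c.key for c in concepts}
    for name, key in (extra_names or {}).items():
        index.setdefault(norm_name(name), key)
    return index


def attach_evidence(associations: list[Association],
                    predications: list[PredicationRow],
                    name_index: dict[str, str],
                    ) -> tuple[list[EvidenceAttachment], EvidenceStats]:
    """Join predications onto associations; returns attachments + counters.

    PharmGKB-sourced PMIDs on the associations themselves are carried
    through as ``provenance=source_file`` attachments; predication
    matches are emitted separately with their predicates.  Matching is
    symmetric in subject/object order.
    """
    pair_set = {assoc.key for assoc in associations}
    matched: dict[tuple[str, str], tuple[set[str], set[str]]] = {}
    stats = EvidenceStats(total=len(associations))

    for pred in predications:
        ks = name_index.get(norm_name(pred.subject_name))
        ko = name_index.get(norm_name(pred.object_name))
        if ks is None or ko is None or ks == ko:
            stats.unresolved_predications += 1
            continue
        pair = (ks, ko) if ks <= ko else (ko, ks)
        if pair not in pair_set:
            stats.unresolved_predications += 1
            continue
        pmids, predicates = matched.setdefault(pair, (set(), set()))
        pmids.add(pred.pmid)
        predicates.add(pred.predicate)

    attachments: list[EvidenceAttachment] = []
    for assoc in associations:
        got = False
        if assoc.pmids:
            attachments.append(EvidenceAttachment(
                pair=assoc.key, pmids=frozenset(assoc.pmids),
                predicates=frozenset(), provenance="source_file"))
            stats.with_source_pmids += 1
            got = True
        if assoc.key in matched:
            pmids, predicates = matched[assoc.key]
            attachments.append(EvidenceAttachment(
                pair=assoc.key, pmids=frozenset(pmids),
                predicates=frozenset(predicates),
                provenance="predication_match"))
            stats.predication_matched += 1
            got = True
        if not got:
            stats.unmatched += 1
    return attachments, stats


def write_evidence_tsv(attachments: list[EvidenceAttachment], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["entity1_key", "entity2_key", "pmids", "predicates",
                    "provenance"])
        for att in sorted(attachments, key=lambda a: (a.pair, a.provenance)):
            w.writerow([att.pair[0], att.pair[1],
                        ";".join(sorted(att.pmids)),
                        ";".join(sorted(att.predicates)), att.provenance])
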