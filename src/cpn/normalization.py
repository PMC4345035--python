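"""Terminology normalization: diseases → SNOMED-CT, drugs → RxNorm.

Three tiers are tried in order for every drug and disease concept:

1. ``source_provided`` — a vocabulary code already present in the
   entity files (PharmGKB ships SNOMED-CT / RxNorm annotations);
2. ``resolver_exact`` — an exact-match terminology resolver.  The
   default implementation is a packaged flat lexicon; any object with
   the same ``lookup`` contract (e.g. a client for an ontology REST
   service constrained to exact matches) can be substituted;
3. ``manual`` — a user-supplied override map for terms curated by hand.

The first tier that produces a code wins and is recorded as the
concept's ``method``.  Genes and variants are already standard (HGNC
symbols, dbSNP rsIDs) and pass through.  Concepts that no tier can map
stay in the network flagged ``unmapped``, with a failure category
assigned by configurable name-pattern rules.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from .model import (
    Concept,
    ConfigurationError,
    EntityRecord,
    NormalizedConcept,
    VOCAB_FOR_CTYPE,
    norm_name,
)


class TermResolver(Protocol):
    """Exact-match term → code lookup for one vocabulary."""

    def lookup(self, name: str, vocabulary: str) -> str | None: ...


class EmptyResolver:
    """Resolver that maps nothing (tier 2 disabled)."""

    def lookup(self, name: str, vocabulary: str) -> str | None:
        return None


class LexiconResolver:
    """Flat-file lexicon resolver honouring the exact-match contract.

    The lexicon TSV has columns (vocabulary, code, preferred_name,
    synonyms); synonyms are ';'-separated.  A lookup succeeds only for a
    case-insensitive, whitespace-collapsed exact match of the preferred
    name or a synonym — mirroring an ``isexactmatch = 1`` REST query, so
    no post-hoc mapping validation is needed.
    """

    def __init__(self, entries: dict[tuple[str, str], str] | None = None):
        self._entries: dict[tuple[str, str], str] = dict(entries or {})

    @classmethod
    def from_tsv(cls, path) -> "LexiconResolver":
        entries: dict[tuple[str, str], str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                voc = row["vocabulary"].strip()
                code = row["code"].strip()
                names = [row["preferred_name"]]
                names += (row.get("synonyms") or "").split(";")
                for name in names:
                    if name.strip():
                        entries[(voc, norm_name(name))] = code
        return cls(entries)

    def add(self, vocabulary: str, name: str, code: str) -> None:
        self._entries[(vocabulary, norm_name(name))] = code

    def lookup(self, name: str, vocabulary: str) -> str | None:
        return self._entries.get((vocabulary, norm_name(name)))


#: ordered (category, pattern) rules for classifying unmapped names;
#: first match wins, otherwise "other"
DEFAULT_FAILURE_RULES: tuple[tuple[str, str], ...] = (
    ("chemical IUPAC name", r"\d+[-,]\w+.*-"),
    ("drug class", r"(?i)\b(analgesics|anesthetics|agents|products|"
                   r"antiinflammatory|antirheumatic|inhibitors)\b"),
    ("too broad", r"(?i)\bdisorders?$"),
    ("too narrow", r"(?i)\b(therapy.related|related acute)\b"),
)


def classify_failure(name: str,
                     rules=DEFAULT_FAILURE_RULES) -> str:
    for category, pattern in rules:
        if re.search(pattern, name):
            return category
    return "other"


@dataclass
class CtypeCoverage:
    total: int = 0
    mapped: int = 0
    methods: Counter = field(default_factory=Counter)

    @property
    def unmapped(self) -> int:
        return self.total - self.mapped

    @property
    def percentage(self) -> float:
        """Percentage mapped, rounded to one decimal (94.7 for 394/416)."""
        return round(100.0 * self.mapped / self.total, 1) if self.total else 0.0


@dataclass
class MappingReport:
    per_ctype: dict[str, CtypeCoverage] = field(default_factory=dict)
    unmapped_names: list[tuple[str, str, str]] = field(default_factory=list)
    # (name, ctype, failure category)

    def summary_lines(self) -> list[str]:
        lines = []
        for ctype in sorted(self.per_ctype):
            cov = self.per_ctype[ctype]
            lines.append(f"{ctype}: {cov.mapped} out of {cov.total} "
                         f"({cov.percentage}%) mapped "
                         f"[{dict(sorted(cov.methods.items()))}]")
        return lines

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["ctype", "total", "mapped", "percentage",
                        "methods", "unmapped_names"])
            for ctype in sorted(self.per_ctype):
                cov = self.per_ctype[ctype]
                bad = ";".join(f"{n}[{cat}]" for n, ct, cat
                               in self.unmapped_names if ct == ctype)
                w.writerow([ctype, cov.total, cov.mapped, cov.percentage,
                            ";".join(f"{m}={c}" for m, c
                                     in sorted(cov.methods.items())), bad])


def _validate_overrides(overrides: dict[str, str]) -> None:
    for name, code in overrides.items():
        if not str(code).isdigit():
            raise ConfigurationError(
                f"manual override for {name!r}: code {code!r} is not a "
                f"numeric RxCUI / SNOMED-CT id")


def normalize_concepts(concepts: dict[str, Concept] | list[Concept],
                       entities: list[EntityRecord] | None = None,
                       resolver: TermResolver | None = None,
                       manual_overrides: dict[str, str] | None = None,
                       failure_rules=DEFAULT_FAILURE_RULES,
                       ) -> tuple[dict[str, NormalizedConcept], MappingReport]:
    """Normalize every concept; returns per-concept outcomes and a report.

    ``entities`` supply tier-1 source-provided codes, ``resolver`` is the
    tier-2 exact-match lookup, ``manual_overrides`` (name → numeric code)
    is tier 3.  Genes/variants pass through with their symbols/rsIDs as
    codes; haplotypes keep their star-allele style names.
    """
    if isinstance(concepts, dict):
        concepts = list(concepts.values())
    resolver = resolver or EmptyResolver()
    overrides = {norm_name(k): str(v)
                 for k, v in (manual_overrides or {}).items()}
    _validate_overrides(overrides)

    entity_codes: dict[tuple[str, str], str] = {}
    for ent in entities or []:
        voc = VOCAB_FOR_CTYPE.get(ent.ctype)
        code = ent.code_for(voc) if voc else None
        if code:
            entity_codes[(ent.ctype, norm_name(ent.name))] = code

    norms: dict[str, NormalizedConcept] = {}
    report = MappingReport()
    for concept in sorted(concepts, key=lambda c: c.key):
        cov = report.per_ctype.setdefault(concept.ctype, CtypeCoverage())
        cov.total += 1
        if concept.ctype in ("gene", "variant"):
            code = (concept.name.upper() if concept.ctype == "gene"
                    else concept.name.lower())
            nc = NormalizedConcept(concept.key, VOCAB_FOR_CTYPE[concept.ctype],
                                   code, "source_provided")
        elif concept.ctype == "haplotype":
            nc = NormalizedConcept(concept.key, "none", concept.name,
                                   "source_provided")
        else:
            vocabulary = VOCAB_FOR_CTYPE[concept.ctype]
            name = norm_name(concept.name)
            code, method = entity_codes.get((concept.ctype, name)), "source_provided"
            if code is None:
                code, method = resolver.lookup(concept.name, vocabulary), "resolver_exact"
            if code is None:
                code, method = overrides.get(name), "manual"
            if code is None:
                method = "unmapped"
                report.unmapped_names.append(
                    (concept.name, concept.ctype,
                     classify_failure(concept.name, failure_rules)))
            nc = NormalizedConcept(concept.key,
                                   vocabulary if code else "none",
                                   code, method)
        norms[concept.key] = nc
        cov.methods[nc.method] += 1
        if nc.code is not None:
            cov.mapped += 1
    return norms, report


def coverage_report(norms: dict[str, NormalizedConcept],
                    concepts: dict[str, Concept] | None = None,
                    failure_rules=DEFAULT_FAILURE_RULES) -> MappingReport:
    """Recompute the coverage report from normalization outcomes alone."""
    report = MappingReport()
    for key in sorted(norms):
        nc = norms[key]
        ctype = (concepts[key].ctype if concepts and key in concepts
                 else key.split(":", 1)[0])
        name = concepts[key].name if concepts and key in concepts else key
        cov = report.per_ctype.setdefault(ctype, CtypeCoverage())
        cov.total += 1
        cov.methods[nc.method] += 1
        if nc.code is not None:
            cov.mapped += 1
        else:
            report.unmapped_names.append(
                (name, ctype, classify_failure(name, failure_rules)))
    return report


def packaged_lexicon() -> LexiconResolver:
    """The small demo lexicon shipped with the package."""
    data = Path(__file__).parent / "data" / "lexicon.tsv"
    return LexiconResolver.from_tsv(data)


def load_overrides_yaml(path) -> dict[str, str]:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: overrides file must be a mapping")
    return {str(k): str(v) for k, v in data.items()}
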