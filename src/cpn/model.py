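"""Shared domain model for the cancer pharmacogenomics network (CPN).

The CPN is a heterogeneous graph whose nodes are typed pharmacogenomic
concepts (drugs, diseases, genes, variants/SNPs, haplotypes) and whose
edges are associations harvested from three resources: a PharmGKB-style
relationships file, the GWAS Catalog, and the FDA pharmacogenomic
biomarker table.  This module defines the record types that flow between
the pipeline stages; parsing, expansion, normalization, evidence and
network assembly live in their own modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class CPNError(Exception):
    """Base class for all package errors."""


class FormatError(CPNError):
    """An input file does not conform to the expected tabular layout."""


class IntegrationError(CPNError):
    """Concepts from different rows/resources cannot be merged consistently."""


class ConfigurationError(CPNError):
    """A configuration value is invalid (bad code syntax, bad enum, ...)."""


class ConceptLookupError(CPNError, KeyError):
    """A requested concept key/name is not present in the graph."""


class UsageError(CPNError):
    """An operation was invoked with semantically wrong arguments."""


#: canonical concept types, in the order used to build pair-type labels
CONCEPT_TYPES = ("drug", "disease", "gene", "variant", "haplotype")

#: labels used in pair-type strings ("variant" nodes are SNPs in the sources)
PAIR_LABEL = {"variant": "snp"}

#: map from source-file type spellings to canonical concept types
SOURCE_TYPE_MAP = {
    "drug": "drug",
    "chemical": "drug",
    "disease": "disease",
    "gene": "gene",
    "variant location": "variant",
    "variant": "variant",
    "snp": "variant",
    "haplotype": "haplotype",
}

#: closed vocabulary list for EntityRecord code maps
VOCABULARIES = ("SNOMED-CT", "RxNorm", "MeSH", "UMLS", "HGNC", "dbSNP")

#: terminology used to normalize each concept type
VOCAB_FOR_CTYPE = {
    "disease": "SNOMED-CT",
    "drug": "RxNorm",
    "gene": "HGNC",
    "variant": "dbSNP",
}

SOURCES = ("pharmgkb", "gwas", "fda")

_WS = re.compile(r"\s+")
_CURLY = str.maketrans({"“": '"', "”": '"', "‘": "'", "’": "'"})

RSID_RE = re.compile(r"^rs\d+$")


def clean_text(text: str) -> str:
    """Trim, collapse internal whitespace and normalize curly quotes."""
    return _WS.sub(" ", text.translate(_CURLY)).strip()


def norm_name(name: str) -> str:
    """Case/whitespace-insensitive canonical form of a concept name."""
    return clean_text(name).casefold()


def canonical_ctype(raw: str) -> str:
    try:
        return SOURCE_TYPE_MAP[norm_name(raw)]
    except KeyError:
        raise FormatError(f"unknown concept type {raw!r}") from None


def concept_key(ctype: str, name: str) -> str:
    """Name-based concept identity, stable under case/whitespace changes."""
    return f"{ctype}:{norm_name(name)}"


def pair_type(ctype1: str, ctype2: str) -> str:
    """Canonical edge label, e.g. ('gene', 'disease') -> 'disease-gene'."""
    i, j = CONCEPT_TYPES.index(ctype1), CONCEPT_TYPES.index(ctype2)
    if i > j:
        i, j = j, i
    a, b = CONCEPT_TYPES[i], CONCEPT_TYPES[j]
    return f"{PAIR_LABEL.get(a, a)}-{PAIR_LABEL.get(b, b)}"


@dataclass(frozen=True)
class RawAssociationRow:
    """One association row from any of the three resources."""

    entity1_id: str
    entity1_name: str
    entity1_type: str  # canonical ctype
    entity2_id: str
    entity2_name: str
    entity2_type: str
    pmids: tuple[str, ...] = ()
    source: str = "pharmgkb"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise FormatError(f"unknown source {self.source!r}")
        for t in (self.entity1_type, self.entity2_type):
            if t not in CONCEPT_TYPES:
                raise FormatError(f"unknown concept type {t!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Unordered pair key (sorted concept keys)."""
        a = concept_key(self.entity1_type, self.entity1_name)
        b = concept_key(self.entity2_type, self.entity2_name)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EntityRecord:
    """A PharmGKB entity-file row: the source-provided vocabulary codes."""

    source_id: str
    name: str
    ctype: str
    codes: tuple[tuple[str, str], ...] = ()  # (vocabulary, code) pairs

    def code_for(self, vocabulary: str) -> str | None:
        for voc, code in self.codes:
            if voc == vocabulary:
                return code
        return None


@dataclass(frozen=True)
class SeedList:
    """Ordered, case-insensitively de-duplicated cancer seed terms."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise FormatError("seed list is empty")
        seen = {norm_name(t) for t in self.terms}
        if len(seen) != len(self.terms):
            raise FormatError("seed list contains case-insensitive duplicates")

    @classmethod
    def from_terms(cls, terms) -> "SeedList":
        out, seen = [], set()
        for t in terms:
            t = clean_text(t)
            if t and norm_name(t) not in seen:
                seen.add(norm_name(t))
                out.append(t)
        return cls(tuple(out))

    @property
    def normalized(self) -> frozenset[str]:
        return frozenset(norm_name(t) for t in self.terms)

    def __len__(self) -> int:
        return len(self.terms)


PREDICATE_RE = re.compile(r"^[A-Za-z_]+$")


@dataclass(frozen=True)
class PredicationRow:
    """A SemMedDB-style subject–predicate–object triple with its PubMed id."""

    subject_name: str
    predicate: str
    object_name: str
    pmid: str


@dataclass(frozen=True)
class Concept:
    """A typed network node."""

    key: str
    name: str
    ctype: str
    sources: frozenset[str] = frozenset()

    @classmethod
    def from_name(cls, ctype: str, name: str, sources=()) -> "Concept":
        return cls(concept_key(ctype, name), clean_text(name), ctype,
                   frozenset(sources))


@dataclass(frozen=True)
class DegreeRecord:
    """Minimal seed distance of a concept and its weight score.

    Degree 1 concepts (direct neighbours of a seed) score 4, degree 2
    scores 3, degree 3 scores 2, degree 4 scores 1; seeds themselves are
    degree 0 and continue the line at weight 5.
    """

    key: str
    degree: int
    weight: int

    @classmethod
    def for_degree(cls, key: str, degree: int) -> "DegreeRecord":
        return cls(key, degree, 5 - degree)


@dataclass
class Association:
    """An unordered concept pair with merged provenance."""

    a: Concept
    b: Concept
    sources: set[str] = field(default_factory=set)
    pmids: set[str] = field(default_factory=set)
    predicates: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str]:
        return ((self.a.key, self.b.key) if self.a.key <= self.b.key
                else (self.b.key, self.a.key))

    @property
    def pair_type(self) -> str:
        return pair_type(self.a.ctype, self.b.ctype)


@dataclass(frozen=True)
class NormalizedConcept:
    """Outcome of terminology normalization for one concept."""

    key: str
    vocabulary: str  # SNOMED-CT | RxNorm | HGNC | dbSNP | none
    code: str | None
    method: str  # source_provided | resolver_exact | manual | unmapped

    def __post_init__(self) -> None:
        if (self.method == "unmapped") != (self.code is None):
            raise ConfigurationError(
                f"{self.key}: method={self.method} inconsistent with code={self.code!r}")


@dataclass(frozen=True)
class EvidenceAttachment:
    """PubMed ids (and predicates) attached to one association."""

    pair: tuple[str, str]
    pmids: frozenset[str]
    predicates: frozenset[str]
    provenance: str  # source_file | predication_match

    def __post_init__(self) -> None:
        if self.provenance == "predication_match" and (
                not self.predicates or not self.pmids):
            raise ConfigurationError(
                f"predication match for {self.pair} lacks pmids or predicates")


@dataclass(frozen=True)
class PathResult:
    """A simple path from a query drug to a candidate disease."""

    nodes: tuple[str, ...]
    length: int
    weight_sum: int
    vip_count: int

    def __post_init__(self) -> None:
        if self.length != len(self.nodes) - 1:
            raise ConfigurationError("path length inconsistent with node list")


@dataclass
class IndicationCandidate:
    """A (drug, disease) repurposing hypothesis with its supporting paths."""

    drug: str
    disease: str
    distance: int
    paths: list[PathResult]
    shortest: PathResult
    novel: bool

    @property
    def rank_score(self) -> tuple:
        """Sort key: shorter, heavier, more VIP edges first; keys break ties."""
        s = self.shortest
        return (s.length, -s.weight_sum, -s.vip_count, self.disease)
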