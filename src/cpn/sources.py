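"""Readers for the five source formats and the cancer seed list.

Every reader returns a :class:`ParseResult` whose ``stats`` account for
each dropped row by reason, so that ``rows_in == rows_kept + dropped``
holds exactly (parsing is lossless modulo the stated filters).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    FormatError,
    PredicationRow,
    PREDICATE_RE,
    RawAssociationRow,
    RSID_RE,
    SeedList,
    EntityRecord,
    VOCABULARIES,
    canonical_ctype,
    clean_text,
    norm_name,
)

log = logging.getLogger(__name__)

#: GWAS placeholder strings that are not real entity names
PLACEHOLDER_NAMES = {"nr", "intergenic", "nd", "-", ""}

PHARMGKB_COLUMNS = ("entity1_id", "entity1_name", "entity1_type",
                    "entity2_id", "entity2_name", "entity2_type", "pmids")

DUMP_COLUMNS = PHARMGKB_COLUMNS + ("source",)


@dataclass(frozen=True)
class TableDialect:
    """Configurable TSV/CSV dialect for the tabular inputs."""

    delimiter: str = "\t"
    quotechar: str = '"'


DEFAULT_DIALECT = TableDialect()


@dataclass
class ParseStats:
    rows_in: int = 0
    rows_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def drop(self, reason: str) -> None:
        self.dropped[reason] += 1

    @property
    def rows_dropped(self) -> int:
        return sum(self.dropped.values())

    def check(self) -> None:
        assert self.rows_in == self.rows_kept + self.rows_dropped


@dataclass
class ParseResult:
    rows: list
    stats: ParseStats


def _header_key(name: str) -> str:
    """Match header cells robustly: 'Entity1_ name' == 'Entity1_name'."""
    return clean_text(name).casefold().replace(" ", "").replace("_", "")


def _read_table(path, dialect: TableDialect) -> tuple[list[dict], dict]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter,
                            quotechar=dialect.quotechar)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: file is empty (no header row)")
        keys = [_header_key(h) for h in header]
        rows = []
        for raw in reader:
            if not any(cell.strip() for cell in raw):
                continue  # skip blank lines
            raw = list(raw) + [""] * (len(keys) - len(raw))
            rows.append({k: clean_text(v) for k, v in zip(keys, raw)})
    return rows, {k: h for k, h in zip(keys, header)}


def _require(columns: dict, needed: dict, path) -> None:
    for key, label in needed.items():
        if key not in columns:
            raise FormatError(f"{path}: missing required column {label!r}")


def _split_multi(cell: str) -> list[str]:
    """Split a multi-valued cell on ',' and ';' and trim the parts."""
    parts = cell.replace(";", ",").split(",")
    return [clean_text(p) for p in parts if clean_text(p)]


def _split_pmids(cell: str) -> tuple[str, ...]:
    out = []
    for tok in cell.replace(",", ";").split(";"):
        tok = tok.strip()
        if tok and tok.isdigit():
            out.append(tok)
    return tuple(out)


def read_pharmgkb_relationships(path, dialect: TableDialect = DEFAULT_DIALECT
                                ) -> ParseResult:
    """Parse a PharmGKB-style relationships file.

    The file must carry the seven columns Entity1_id, Entity1_name,
    Entity1_type, Entity2_id, Entity2_name, Entity2_type, PMIDs.  The
    PMIDs cell is ';'-separated.  Rows with a missing entity name are
    dropped and counted.
    """
    rows, columns = _read_table(path, dialect)
    _require(columns, {_header_key(k): k for k in
                       ("Entity1_id", "Entity1_name", "Entity1_type",
                        "Entity2_id", "Entity2_name", "Entity2_type",
                        "PMIDs")}, path)
    stats = ParseStats(rows_in=len(rows))
    out: list[RawAssociationRow] = []
    for r in rows:
        n1, n2 = r["entity1name"], r["entity2name"]
        if norm_name(n1) in PLACEHOLDER_NAMES or norm_name(n2) in PLACEHOLDER_NAMES:
            stats.drop("missing_name")
            continue
        try:
            t1 = canonical_ctype(r["entity1type"])
            t2 = canonical_ctype(r["entity2type"])
        except FormatError:
            stats.drop("bad_type")
            continue
        out.append(RawAssociationRow(
            entity1_id=r["entity1id"], entity1_name=n1, entity1_type=t1,
            entity2_id=r["entity2id"], entity2_name=n2, entity2_type=t2,
            pmids=_split_pmids(r["pmids"]), source="pharmgkb"))
        stats.rows_kept += 1
    if not rows:
        log.warning("%s: no data rows", path)
    stats.check()
    return ParseResult(out, stats)


def read_gwas_catalog(path, seeds: SeedList,
                      dialect: TableDialect = DEFAULT_DIALECT) -> ParseResult:
    """Parse a GWAS-Catalog-style table, keeping only seed traits.

    Each record whose "Disease/Trait" matches a seed (case- and
    whitespace-insensitively) yields one disease–gene row per reported
    gene, one disease–SNP row per SNP, and one gene–SNP row per
    (gene, SNP) combination within the record.  Malformed SNP ids (not
    ``rs`` + digits) are skipped with a warning.
    """
    rows, columns = _read_table(path, dialect)
    _require(columns, {"disease/trait": "Disease/Trait",
                       "reportedgene(s)": "Reported Gene(s)",
                       "snps": "SNPs"}, path)
    seed_names = seeds.normalized
    stats = ParseStats(rows_in=len(rows))
    out: list[RawAssociationRow] = []

    def row(id1, n1, t1, id2, n2, t2):
        return RawAssociationRow(entity1_id=id1, entity1_name=n1,
                                 entity1_type=t1, entity2_id=id2,
                                 entity2_name=n2, entity2_type=t2,
                                 pmids=(), source="gwas")

    for r in rows:
        trait = r["disease/trait"]
        if norm_name(trait) not in seed_names:
            stats.drop("trait_not_seed")
            continue
        genes = [g for g in _split_multi(r["reportedgene(s)"])
                 if norm_name(g) not in PLACEHOLDER_NAMES]
        snps = []
        for s in _split_multi(r["snps"]):
            if RSID_RE.match(s):
                snps.append(s)
            else:
                log.warning("%s: malformed SNP id %r skipped", path, s)
        for g in genes:
            out.append(row(trait, trait, "disease", g, g, "gene"))
        for s in snps:
            out.append(row(trait, trait, "disease", s, s, "variant"))
            for g in genes:
                out.append(row(g, g, "gene", s, s, "variant"))
        stats.rows_kept += 1
    stats.check()
    return ParseResult(out, stats)


def read_fda_biomarkers(path, dialect: TableDialect = DEFAULT_DIALECT
                        ) -> ParseResult:
    """Parse an FDA biomarker table, keeping Oncology rows as drug–gene pairs."""
    rows, columns = _read_table(path, dialect)
    _require(columns, {"therapeuticareas": "Therapeutic areas",
                       "hugosymbol": "HUGO Symbol"}, path)
    drug_col = next((k for k in ("drug", "drugname", "drugs") if k in columns),
                    None)
    if drug_col is None:
        raise FormatError(f"{path}: missing required column 'Drug'")
    stats = ParseStats(rows_in=len(rows))
    out: list[RawAssociationRow] = []
    for r in rows:
        if "oncology" not in r["therapeuticareas"].casefold():
            stats.drop("not_oncology")
            continue
        drug = r[drug_col]
        if norm_name(drug) in PLACEHOLDER_NAMES:
            stats.drop("missing_name")
            continue
        for g in _split_multi(r["hugosymbol"]):
            if norm_name(g) in PLACEHOLDER_NAMES:
                continue
            out.append(RawAssociationRow(
                entity1_id=drug, entity1_name=drug, entity1_type="drug",
                entity2_id=g, entity2_name=g, entity2_type="gene",
                pmids=(), source="fda"))
        stats.rows_kept += 1
    stats.check()
    return ParseResult(out, stats)


def read_predications(path, dialect: TableDialect = DEFAULT_DIALECT
                      ) -> ParseResult:
    """Parse a PREDICATION-style table into de-duplicated triples."""
    rows, columns = _read_table(path, dialect)
    names = {"subject": ("subject", "subjectname", "subject_name"),
             "predicate": ("predicate",),
             "object": ("object", "objectname", "object_name"),
             "pmid": ("pmid", "pmids")}
    resolved = {}
    for field_name, options in names.items():
        col = next((o for o in options if o in columns), None)
        if col is None:
            raise FormatError(f"{path}: missing required column {field_name!r}")
        resolved[field_name] = col
    stats = ParseStats(rows_in=len(rows))
    seen: set[tuple] = set()
    out: list[PredicationRow] = []
    for r in rows:
        subj, pred = r[resolved["subject"]], r[resolved["predicate"]]
        obj, pmid = r[resolved["object"]], r[resolved["pmid"]]
        if not pred:
            stats.drop("blank_predicate")
            continue
        if not (subj and obj and pmid) or not PREDICATE_RE.match(pred):
            stats.drop("malformed")
            continue
        tup = (subj, pred, obj, pmid)
        if tup in seen:
            stats.drop("duplicate")
            continue
        seen.add(tup)
        out.append(PredicationRow(subj, pred, obj, pmid))
        stats.rows_kept += 1
    stats.check()
    return ParseResult(out, stats)


def read_seed_list(path) -> SeedList:
    """Read one cancer term per line; '#' starts a comment."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"seed list not found: {path}")
    terms = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = clean_text(line.split("#", 1)[0])
        if line:
            terms.append(line)
    return SeedList.from_terms(terms)


def read_entities(path, dialect: TableDialect = DEFAULT_DIALECT
                  ) -> list[EntityRecord]:
    """Read a PharmGKB-style entity file (Entity_id, Name, Type + vocab columns)."""
    rows, columns = _read_table(path, dialect)
    _require(columns, {"entityid": "Entity_id", "name": "Name",
                       "type": "Type"}, path)
    vocab_cols = {v: _header_key(v) for v in VOCABULARIES
                  if _header_key(v) in columns}
    out = []
    for r in rows:
        if not r["name"]:
            continue
        codes = tuple((voc, r[col]) for voc, col in vocab_cols.items()
                      if r[col])
        out.append(EntityRecord(source_id=r["entityid"], name=r["name"],
                                ctype=canonical_ctype(r["type"]), codes=codes))
    return out


def packaged_example() -> tuple[Path, Path]:
    """Paths of the packaged worked-example fixture (relationships, seeds)."""
    data = Path(__file__).parent / "data"
    return data / "example_relationships.tsv", data / "example_seeds.txt"


def dump_parsed(rows: list[RawAssociationRow], path) -> None:
    """Write parsed association rows to a canonical TSV for audit."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["Entity1_id", "Entity1_name", "Entity1_type",
                    "Entity2_id", "Entity2_name", "Entity2_type",
                    "PMIDs", "Source"])
        for r in rows:
            w.writerow([r.entity1_id, r.entity1_name, r.entity1_type,
                        r.entity2_id, r.entity2_name, r.entity2_type,
                        ";".join(r.pmids), r.source])


def load_parsed(path) -> list[RawAssociationRow]:
    """Read back a canonical dump; round-trips the row multiset exactly."""
    rows, columns = _read_table(path, TableDialect())
    _require(columns, {"source": "Source"}, path)
    out = []
    for r in rows:
        out.append(RawAssociationRow(
            entity1_id=r["entity1id"], entity1_name=r["entity1name"],
            entity1_type=r["entity1type"], entity2_id=r["entity2id"],
            entity2_name=r["entity2name"], entity2_type=r["entity2type"],
            pmids=_split_pmids(r["pmids"]), source=r["source"]))
    return out
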