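"""End-to-end orchestration: parse → expand → filter → normalize →
evidence → assemble → export → infer indications.

``run_pipeline`` executes the stages in order against a
:class:`PipelineConfig`, writes all artifacts into the output
directory, and returns a :class:`PipelineResult` whose manifest records
every drop/merge/mapping counter (inputs = kept + dropped holds at
every stage).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import evidence as ev
from . import expansion as ex
from . import network as net
from . import normalization as norm
from . import repurposing as rep
from . import sources as src
from .model import Association, Concept, ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    relationships: str
    seeds: str
    outdir: str
    entities: str | None = None
    gwas: str | None = None
    fda: str | None = None
    predications: str | None = None
    lexicon: str | None = None
    overrides: str | None = None
    known_indications: str | None = None
    vip_pairs: str | None = None
    max_degree: int = 4
    gwas_filter_mode: str = "any"  # any | both
    strict_matrix: bool = True
    radius: int = 3
    query_drugs: tuple[str, ...] = ()
    dump_parsed: bool = False

    def validate(self) -> None:
        for name in ("relationships", "seeds", "entities", "gwas", "fda",
                     "predications", "lexicon", "overrides",
                     "known_indications", "vip_pairs"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{name}: file not found: {path}")
        if self.gwas_filter_mode not in ("any", "both"):
            raise ConfigurationError(
                f"gwas_filter_mode must be 'any' or 'both', "
                f"got {self.gwas_filter_mode!r}")
        if self.max_degree < 1 or self.radius < 1:
            raise ConfigurationError("max_degree and radius must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        if "query_drugs" in data and isinstance(data["query_drugs"], list):
            data["query_drugs"] = tuple(data["query_drugs"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None


@dataclass
class PipelineResult:
    manifest: dict
    expansion: ex.ExpansionResult
    gwas_rows: list
    fda_rows: list
    norms: dict
    report: norm.MappingReport
    attachments: list
    evidence_stats: ev.EvidenceStats
    cpn: net.CPNGraph
    candidates: dict[str, list] = field(default_factory=dict)


def rows_to_associations(rows) -> list[Association]:
    """Merge raw rows into unordered-pair associations (pmids unioned)."""
    merged: dict[tuple[str, str], Association] = {}
    for row in rows:
        c1 = Concept.from_name(row.entity1_type, row.entity1_name,
                               sources=(row.source,))
        c2 = Concept.from_name(row.entity2_type, row.entity2_name,
                               sources=(row.source,))
        if c1.key == c2.key:
            continue
        a, b = sorted((c1, c2), key=lambda c: c.key)
        key = (a.key, b.key)
        if key in merged:
            merged[key].sources.add(row.source)
            merged[key].pmids.update(row.pmids)
        else:
            merged[key] = Association(a=a, b=b, sources={row.source},
                                      pmids=set(row.pmids))
    return [merged[k] for k in sorted(merged)]


def _stage(manifest: dict, name: str, **counts) -> None:
    manifest["stages"][name] = counts
    log.info("stage=%s %s", name,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; nonzero counters land in the returned manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in dataclasses.asdict(config).items()},
                      "stages": {}, "outputs": {}, "warnings": []}

    # -- parse -------------------------------------------------------------
    seeds = src.read_seed_list(config.seeds)
    rel = src.read_pharmgkb_relationships(config.relationships)
    _stage(manifest, "parse_relationships", rows_in=rel.stats.rows_in,
           rows_kept=rel.stats.rows_kept, dropped=dict(rel.stats.dropped))
    entities = src.read_entities(config.entities) if config.entities else []
    gwas = (src.read_gwas_catalog(config.gwas, seeds) if config.gwas
            else src.ParseResult([], src.ParseStats()))
    _stage(manifest, "parse_gwas", rows_in=gwas.stats.rows_in,
           rows_kept=gwas.stats.rows_kept, pairs=len(gwas.rows),
           dropped=dict(gwas.stats.dropped))
    fda = (src.read_fda_biomarkers(config.fda) if config.fda
           else src.ParseResult([], src.ParseStats()))
    _stage(manifest, "parse_fda", rows_in=fda.stats.rows_in,
           rows_kept=fda.stats.rows_kept, pairs=len(fda.rows),
           dropped=dict(fda.stats.dropped))
    preds = (src.read_predications(config.predications)
             if config.predications
             else src.ParseResult([], src.ParseStats()))
    _stage(manifest, "parse_predications", rows_in=preds.stats.rows_in,
           rows_kept=preds.stats.rows_kept, dropped=dict(preds.stats.dropped))
    if config.dump_parsed:
        dump = outdir / "parsed_rows.tsv"
        src.dump_parsed(rel.rows + gwas.rows + fda.rows, dump)
        manifest["outputs"]["parsed_rows"] = str(dump)

    # -- expand ------------------------------------------------------------
    expansion = ex.expand_from_seeds(rel.rows, seeds,
                                     max_degree=config.max_degree)
    max_deg = max((r.degree for r in expansion.degrees.values()), default=0)
    _stage(manifest, "expand", input_pairs=len(rel.rows),
           concepts=len(expansion.concepts),
           associations=len(expansion.associations),
           max_degree_observed=max_deg,
           self_loops_dropped=expansion.dropped_self_loops,
           unresolved_seeds=len(expansion.unresolved_seeds))
    manifest["warnings"] += [f"unresolved seed: {t}"
                             for t in expansion.unresolved_seeds]

    # -- GWAS co-occurrence filter ------------------------------------------
    gwas_kept = ex.apply_gwas_cooccurrence_filter(
        gwas.rows, expansion.keys, mode=config.gwas_filter_mode)
    _stage(manifest, "gwas_cooccurrence", rows_in=len(gwas.rows),
           rows_kept=len(gwas_kept), dropped=len(gwas.rows) - len(gwas_kept),
           mode=config.gwas_filter_mode)

    # -- normalize -----------------------------------------------------------
    concepts = dict(expansion.concepts)
    for row in gwas_kept + fda.rows:
        for ctype, name in ((row.entity1_type, row.entity1_name),
                            (row.entity2_type, row.entity2_name)):
            c = Concept.from_name(ctype, name, sources=(row.source,))
            concepts.setdefault(c.key, c)
    resolver = (norm.LexiconResolver.from_tsv(config.lexicon)
                if config.lexicon else norm.EmptyResolver())
    overrides = (norm.load_overrides_yaml(config.overrides)
                 if config.overrides else {})
    norms, report = norm.normalize_concepts(concepts, entities, resolver,
                                            overrides)
    coverage = {ctype: {"total": cov.total, "mapped": cov.mapped,
                        "percentage": cov.percentage}
                for ctype, cov in report.per_ctype.items()}
    _stage(manifest, "normalize", concepts=len(norms), **{
        f"{ct}_pct": cov["percentage"] for ct, cov in sorted(coverage.items())})
    manifest["stages"]["normalize"]["coverage"] = coverage
    report.write_tsv(outdir / "mapping_report.tsv")
    manifest["outputs"]["mapping_report"] = str(outdir / "mapping_report.tsv")

    # -- evidence ------------------------------------------------------------
    associations = (list(expansion.associations)
                    + rows_to_associations(gwas_kept + fda.rows))
    name_index = ev.build_name_index(concepts)
    attachments, estats = ev.attach_evidence(associations, preds.rows,
                                             name_index)
    _stage(manifest, "evidence", associations=estats.total,
           with_source_pmids=estats.with_source_pmids,
           predication_matched=estats.predication_matched,
           unmatched=estats.unmatched,
           unresolved_predications=estats.unresolved_predications)
    ev.write_evidence_tsv(attachments, outdir / "evidence.tsv")
    manifest["outputs"]["evidence"] = str(outdir / "evidence.tsv")

    # -- assemble ------------------------------------------------------------
    vip = (rep.load_vip_pairs(config.vip_pairs) if config.vip_pairs
           else set())
    cpn = net.build_cpn(expansion, gwas_kept, fda.rows, norms=norms,
                        evidence=attachments, strict=config.strict_matrix,
                        vip_pairs=vip)
    stats = cpn.stats()
    _stage(manifest, "build", **{k: v for k, v in stats.items()
                                 if isinstance(v, int)})
    manifest["stages"]["build"].update(stats)
    for fmt, fname in (("graphml", "cpn.graphml"), ("sif", "cpn.sif"),
                       ("tsv", "cpn")):
        net.export_graph(cpn, fmt, outdir / fname)
    manifest["outputs"].update({
        "graphml": str(outdir / "cpn.graphml"), "sif": str(outdir / "cpn.sif"),
        "nodes": str(outdir / "cpn.nodes.tsv"),
        "edges": str(outdir / "cpn.edges.tsv")})

    # -- repurposing ---------------------------------------------------------
    known = (rep.load_known_indications(config.known_indications, cpn)
             if config.known_indications else {})
    candidates: dict[str, list] = {}
    for drug in config.query_drugs:
        node = cpn.require_node(drug)
        cands = rep.infer_indications(cpn, node, radius=config.radius,
                                      known=known.get(node, set()))
        candidates[drug] = cands
        out = outdir / f"candidates_{drug.replace(' ', '_')}.tsv"
        rep.write_candidates_tsv(cands, out)
        manifest["outputs"][f"candidates:{drug}"] = str(out)
        _stage(manifest, f"repurpose:{drug}", candidates=len(cands),
               novel=sum(c.novel for c in cands))

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = str(manifest_path)

    return PipelineResult(manifest=manifest, expansion=expansion,
                          gwas_rows=gwas_kept, fda_rows=fda.rows,
                          norms=norms, report=report,
                          attachments=attachments, evidence_stats=estats,
                          cpn=cpn, candidates=candidates)
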