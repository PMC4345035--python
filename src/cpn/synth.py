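"""Synthetic emulation of the five source resources, with ground truth.

The generator plants the structures the pipeline is supposed to
recover and writes them in the exact file formats the readers expect:

* multi-degree association chains in the PharmGKB-style relationships
  file, following the worked seed-chain pattern
  disease → variant → disease → gene → drug (degrees 1–4), optionally
  extended past the degree cap;
* drug → gene → disease repurposing paths whose planted drug reaches a
  planted "novel" disease at edge distance 2 and its known indication
  (a seed) at the same distance;
* GWAS Catalog records whose traits are seeds, reusing a configurable
  fraction of planted PharmGKB genes/SNPs (cross-resource overlap);
* FDA biomarker rows ("Oncology" area) overlapping planted drugs/genes,
  plus a non-oncology decoy row;
* SemMedDB-style predications covering a configurable fraction of the
  GWAS/FDA pairs, drawn from the predicate inventories observed for
  each resource;
* a seed list, a flat lexicon, manual overrides, known indications and
  one VIP pair flag.

Every planted fact is recorded in :class:`GroundTruth`; identical
config + seed produce byte-identical files.  Concept names come from
disjoint per-type alphabets (``DRUG_###``, ``Disease_###``, ``GENE###``,
``rs#####``, ``HAP*#``) so identity collisions are impossible unless
planted.  A configurable fraction of drug names are deliberately
IUPAC-like or class-like so the normalization failure categories are
exercised.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import ConfigurationError, concept_key

GWAS_PREDICATES = ("AFFECTS", "ASSOCIATED_WITH", "AUGMENTS", "CAUSES",
                   "NEG_ASSOCIATED_WITH", "NEG_PART_OF", "PART_OF",
                   "PREDISPOSES")
FDA_PREDICATES = ("COEXISTS_WITH", "compared_with", "higher_than",
                  "INHIBITS", "INTERACTS_WITH", "USES")

_TIERS = ("source_provided", "resolver_exact", "manual")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic bundle (desk scale)."""

    rng_seed: int = 0
    n_seed_terms: int = 3
    n_chains: int = 4           # seed-chain pattern, degrees 1..4
    n_repurposing: int = 2      # planted drug->gene->disease paths
    n_beyond_cap: int = 1       # chains extended one hop past the cap
    n_gwas_records: int = 4
    n_fda_records: int = 3
    cross_resource_overlap: float = 0.5
    evidence_fraction: float = 0.5
    unmapped_fraction: float = 0.15
    max_degree: int = 4

    def validate(self) -> None:
        for name in ("cross_resource_overlap", "evidence_fraction",
                     "unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_seed_terms", "n_chains", "n_repurposing",
                     "n_beyond_cap", "n_gwas_records", "n_fda_records"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_seed_terms < 1:
            raise ConfigurationError("need at least one seed term")
        if self.max_degree < 1:
            raise ConfigurationError("max_degree must be >= 1")
        if self.cross_resource_overlap > 0 and self.n_chains == 0:
            raise ConfigurationError(
                "cross_resource_overlap > 0 requires planted chains to "
                "overlap with (n_chains is 0)")
        if self.n_beyond_cap > self.n_chains:
            raise ConfigurationError("n_beyond_cap cannot exceed n_chains")


@dataclass
class GroundTruth:
    """Every planted fact, keyed the way the pipeline reports it."""

    degrees: dict[str, int] = field(default_factory=dict)
    beyond_cap: list[str] = field(default_factory=list)
    pairs: list[list[str]] = field(default_factory=list)  # [k1, k2, source]
    mapping: dict[str, dict] = field(default_factory=dict)
    evidence: dict[str, dict] = field(default_factory=dict)  # "k1|k2" -> facts
    repurposing: list[dict] = field(default_factory=list)
    coverage: dict[str, dict] = field(default_factory=dict)
    query_drugs: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


class _Namer:
    """Deterministic disjoint name factories per concept type."""

    def __init__(self) -> None:
        self.counts = {"drug": 0, "disease": 0, "gene": 0, "variant": 0,
                       "haplotype": 0, "iupac": 0, "class": 0}

    def _next(self, kind: str) -> int:
        self.counts[kind] += 1
        return self.counts[kind]

    def drug(self) -> str:
        return f"DRUG_{self._next('drug'):03d}"

    def disease(self) -> str:
        return f"Disease_{self._next('disease'):03d}"

    def gene(self) -> str:
        return f"GENE{self._next('gene'):03d}"

    def variant(self) -> str:
        return f"rs{10000 + self._next('variant')}"

    def haplotype(self) -> str:
        return f"HAP*{self._next('haplotype')}"

    def iupac_drug(self) -> str:
        k = self._next("iupac")
        return f"{k}-methyloxy-{k + 3}-sulfone-benzene"

    def class_drug(self) -> str:
        return f"Analgesics and Anesthetics Products {self._next('class')}"


def _write_tsv(path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        w.writerows(rows)


def _bfs_degrees(pairs, seed_keys):
    """Generator-side bookkeeping BFS (independent of the pipeline)."""
    adj: dict[str, set[str]] = {}
    for k1, k2 in pairs:
        adj.setdefault(k1, set()).add(k2)
        adj.setdefault(k2, set()).add(k1)
    # seeds absent from the association table never enter the network
    dist = {k: 0 for k in seed_keys if k in adj}
    frontier = [k for k in seed_keys if k in adj]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def generate_bundle(config: GeneratorConfig, outdir
                    ) -> tuple[dict[str, Path], GroundTruth]:
    """Write a full synthetic bundle under ``outdir``; return paths + truth."""
    config.validate()
    rng = random.Random(config.rng_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    namer = _Namer()
    truth = GroundTruth()

    # concept plans: name -> (ctype, tier, code, vocabulary)
    plans: dict[str, tuple[str, str, str | None, str]] = {}
    snomed_next, rxcui_next = [20000000], [600000]

    def plan(name: str, ctype: str, tier: str | None = None) -> str:
        if name in plans:
            return name
        if ctype == "disease":
            tier = tier or rng.choice(_TIERS)
            snomed_next[0] += 1
            plans[name] = (ctype, tier, str(snomed_next[0]), "SNOMED-CT")
        elif ctype == "drug":
            if tier == "unmapped":
                plans[name] = (ctype, "unmapped", None, "none")
            else:
                tier = tier or rng.choice(_TIERS)
                rxcui_next[0] += 1
                plans[name] = (ctype, tier, str(rxcui_next[0]), "RxNorm")
        else:
            plans[name] = (ctype, "source_provided", None, "none")
        return name

    # ---- seeds -----------------------------------------------------------
    seeds = [plan(namer.disease(), "disease", tier="source_provided")
             for _ in range(config.n_seed_terms)]

    pharm_pairs: list[tuple[str, str, str, str, tuple[str, ...]]] = []
    # (name1, ctype1, name2, ctype2, pmids)

    def pmids(n=1) -> tuple[str, ...]:
        return tuple(str(rng.randrange(10_000_000, 100_000_000))
                     for _ in range(n))

    # ---- seed chains: disease - variant - disease - gene - drug ----------
    chain_genes: list[str] = []
    chain_drugs: list[str] = []
    chain_variants: list[str] = []
    for i in range(config.n_chains):
        seed = seeds[i % len(seeds)]
        v = plan(namer.variant(), "variant")
        if rng.random() < config.unmapped_fraction:
            name = (namer.iupac_drug() if rng.random() < 0.5
                    else namer.class_drug())
            dr = plan(name, "drug", tier="unmapped")
        else:
            dr = plan(namer.drug(), "drug")
        d2 = plan(namer.disease(), "disease")
        g = plan(namer.gene(), "gene")
        pharm_pairs += [(seed, "disease", v, "variant", pmids()),
                        (v, "variant", d2, "disease", pmids()),
                        (d2, "disease", g, "gene", pmids(2)),
                        (g, "gene", dr, "drug", pmids())]
        if i % 2 == 0:  # exercise the haplotype node type
            hap = plan(namer.haplotype(), "haplotype")
            pharm_pairs.append((d2, "disease", hap, "haplotype", pmids()))
        chain_genes.append(g)
        chain_drugs.append(dr)
        chain_variants.append(v)
        if i < config.n_beyond_cap:
            g5 = plan(namer.gene(), "gene")
            pharm_pairs.append((dr, "drug", g5, "gene", pmids()))
            truth.beyond_cap.append(concept_key("gene", g5))

    # ---- planted repurposing paths: seed - gene - DRUG - gene - disease --
    known_indications: list[tuple[str, str]] = []
    vip_pairs: list[tuple[str, str]] = []
    for j in range(config.n_repurposing):
        s = seeds[j % len(seeds)]
        ga = plan(namer.gene(), "gene")
        dq = plan(namer.drug(), "drug", tier="resolver_exact")
        gb = plan(namer.gene(), "gene")
        x = plan(namer.disease(), "disease", tier="resolver_exact")
        pharm_pairs += [(s, "disease", ga, "gene", pmids()),
                        (ga, "gene", dq, "drug", pmids()),
                        (dq, "drug", gb, "gene", pmids()),
                        (gb, "gene", x, "disease", pmids())]
        known_indications.append((dq, s))
        truth.repurposing += [
            {"drug": dq, "disease": x, "distance": 2, "novel": True},
            {"drug": dq, "disease": s, "distance": 2, "novel": False}]
        truth.query_drugs.append(dq)
        if j == 0:
            vip_pairs.append((concept_key("gene", ga),
                              concept_key("drug", dq)))

    # ---- degrees over the planted PharmGKB graph -------------------------
    seed_keys = [concept_key("disease", s) for s in seeds]
    all_pharm_keys = [(concept_key(t1, n1), concept_key(t2, n2))
                      for n1, t1, n2, t2, _ in pharm_pairs]
    dist = _bfs_degrees(all_pharm_keys, seed_keys)
    retained = {k for k, d in dist.items() if d <= config.max_degree}
    truth.degrees = {k: d for k, d in sorted(dist.items())
                     if d <= config.max_degree}
    for k1, k2 in all_pharm_keys:
        if k1 in retained and k2 in retained:
            a, b = sorted((k1, k2))
            truth.pairs.append([a, b, "pharmgkb"])

    # ---- GWAS records ----------------------------------------------------
    # rows both of whose endpoints are unknown to the PharmGKB expansion
    # are expected casualties of the co-occurrence filter (mode "any")
    gwas_records: list[tuple[str, list[str], list[str]]] = []
    gwas_pairs: list[tuple[str, str, str, str]] = []
    for r in range(config.n_gwas_records):
        trait = seeds[r % len(seeds)]
        genes = []
        for _ in range(1 + (rng.random() < 0.5)):
            if chain_genes and rng.random() < config.cross_resource_overlap:
                g = rng.choice(chain_genes)
            else:
                g = plan(namer.gene(), "gene")
            if g not in genes:
                genes.append(g)
        if chain_variants and rng.random() < config.cross_resource_overlap:
            snp = rng.choice(chain_variants)
        else:
            snp = plan(namer.variant(), "variant")
        written_trait = trait.upper() if r % 2 else trait  # case-insens. match
        gwas_records.append((written_trait, genes, [snp]))
        candidates = [(trait, "disease", g, "gene") for g in genes]
        candidates += [(g, "gene", snp, "variant") for g in genes]
        candidates.append((trait, "disease", snp, "variant"))
        for n1, t1, n2, t2 in candidates:
            if (concept_key(t1, n1) in retained
                    or concept_key(t2, n2) in retained):
                gwas_pairs.append((n1, t1, n2, t2))

    # ---- FDA biomarker rows ----------------------------------------------
    fda_records: list[tuple[str, str, list[str]]] = []
    fda_pairs: list[tuple[str, str, str, str]] = []
    for f in range(config.n_fda_records):
        if chain_drugs and rng.random() < config.cross_resource_overlap:
            drug = rng.choice(chain_drugs)
        else:
            drug = plan(namer.drug(), "drug",
                        tier=rng.choice(("resolver_exact", "manual")))
        genes = []
        for _ in range(1 + (rng.random() < 0.4)):
            if chain_genes and rng.random() < config.cross_resource_overlap:
                g = rng.choice(chain_genes)
            else:
                g = plan(namer.gene(), "gene")
            if g not in genes:
                genes.append(g)
        fda_records.append((drug, "Oncology", genes))
        for g in genes:
            fda_pairs.append((drug, "drug", g, "gene"))
    fda_records.append(("DECOY_DRUG", "Psychiatry", ["DECOYGENE"]))

    # ---- evidence predications ------------------------------------------
    predications: list[tuple[str, str, str, str]] = []
    seen_ev: set[tuple[str, str]] = set()
    for pairs, predicate_pool in ((gwas_pairs, GWAS_PREDICATES),
                                  (fda_pairs, FDA_PREDICATES)):
        for n1, t1, n2, t2 in pairs:
            k1, k2 = sorted((concept_key(t1, n1), concept_key(t2, n2)))
            if (k1, k2) in seen_ev:
                continue
            seen_ev.add((k1, k2))
            if rng.random() >= config.evidence_fraction:
                continue
            ev_pmids, ev_preds = set(), set()
            for _ in range(1 + (rng.random() < 0.5)):
                pred = rng.choice(predicate_pool)
                pmid = str(rng.randrange(10_000_000, 100_000_000))
                subj, obj = (n1, n2) if rng.random() < 0.5 else (n2, n1)
                predications.append((subj, pred, obj, pmid))
                ev_pmids.add(pmid)
                ev_preds.add(pred)
            truth.evidence[f"{k1}|{k2}"] = {
                "pmids": sorted(ev_pmids), "predicates": sorted(ev_preds)}
    predications.append(("Unplanted_concept", "ASSOCIATED_WITH",
                         "Another_unplanted", "99999999"))

    # ---- ground truth: cross-resource pairs, mapping, coverage -----------
    for n1, t1, n2, t2 in gwas_pairs:
        a, b = sorted((concept_key(t1, n1), concept_key(t2, n2)))
        truth.pairs.append([a, b, "gwas"])
    for n1, t1, n2, t2 in fda_pairs:
        a, b = sorted((concept_key(t1, n1), concept_key(t2, n2)))
        truth.pairs.append([a, b, "fda"])

    network_keys = set(retained)
    for n1, t1, n2, t2 in gwas_pairs + fda_pairs:
        network_keys.add(concept_key(t1, n1))
        network_keys.add(concept_key(t2, n2))

    cov: dict[str, list[int]] = {"drug": [0, 0], "disease": [0, 0]}
    for name, (ctype, tier, code, vocab) in sorted(plans.items()):
        key = concept_key(ctype, name)
        if key not in network_keys or ctype not in ("drug", "disease"):
            continue
        truth.mapping[key] = {"method": tier, "code": code,
                              "vocabulary": vocab if code else "none"}
        cov[ctype][0] += 1
        cov[ctype][1] += int(code is not None)
    for ctype, (total, mapped) in cov.items():
        truth.coverage[ctype] = {
            "total": total, "mapped": mapped,
            "percentage": round(100.0 * mapped / total, 1) if total else 0.0}

    # ---- write the files -------------------------------------------------
    paths = {name: outdir / fname for name, fname in (
        ("relationships", "pharmgkb_relationships.tsv"),
        ("entities", "pharmgkb_entities.tsv"),
        ("gwas", "gwas_catalog.tsv"),
        ("fda", "fda_biomarkers.tsv"),
        ("predications", "predications.tsv"),
        ("seeds", "seeds.txt"),
        ("lexicon", "lexicon.tsv"),
        ("overrides", "overrides.yaml"),
        ("known_indications", "known_indications.tsv"),
        ("vip_pairs", "vip_pairs.tsv"),
        ("ground_truth", "ground_truth.json"))}

    pa_ids = {name: f"PA{50000 + i}" for i, name in enumerate(sorted(plans))}

    def src_id(name: str, ctype: str) -> str:
        return name if ctype in ("variant", "haplotype", "gene") \
            else pa_ids[name]

    type_label = {"drug": "Drug", "disease": "Disease", "gene": "Gene",
                  "variant": "Variant location", "haplotype": "Haplotype"}
    _write_tsv(paths["relationships"],
               ["Entity1_id", "Entity1_name", "Entity1_type", "Entity2_id",
                "Entity2_name", "Entity2_type", "PMIDs"],
               [[src_id(n1, t1), n1, type_label[t1], src_id(n2, t2), n2,
                 type_label[t2], ";".join(p)]
                for n1, t1, n2, t2, p in pharm_pairs])

    entity_rows = []
    for name, (ctype, tier, code, vocab) in sorted(plans.items()):
        if ctype not in ("drug", "disease", "gene"):
            continue
        snomed = code if (tier == "source_provided" and vocab == "SNOMED-CT") else ""
        rxnorm = code if (tier == "source_provided" and vocab == "RxNorm") else ""
        entity_rows.append([src_id(name, ctype), name, type_label[ctype],
                            snomed, rxnorm])
    _write_tsv(paths["entities"],
               ["Entity_id", "Name", "Type", "SNOMED-CT", "RxNorm"],
               entity_rows)

    _write_tsv(paths["gwas"], ["Disease/Trait", "Reported Gene(s)", "SNPs"],
               [[trait, ", ".join(genes), "; ".join(snps)]
                for trait, genes, snps in gwas_records])

    _write_tsv(paths["fda"], ["Drug", "Therapeutic areas", "HUGO Symbol"],
               [[drug, area, "; ".join(genes)]
                for drug, area, genes in fda_records])

    _write_tsv(paths["predications"],
               ["subject", "predicate", "object", "pmid"], predications)

    with open(paths["seeds"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic cancer seed terms\n")
        fh.writelines(s + "\n" for s in seeds)

    lexicon_rows = []
    for name, (ctype, tier, code, vocab) in sorted(plans.items()):
        if tier == "resolver_exact":
            lexicon_rows.append([vocab, code, name, ""])
    _write_tsv(paths["lexicon"],
               ["vocabulary", "code", "preferred_name", "synonyms"],
               lexicon_rows)

    with open(paths["overrides"], "w", encoding="utf-8") as fh:
        fh.write("# manual terminology overrides (name: code)\n")
        for name, (ctype, tier, code, vocab) in sorted(plans.items()):
            if tier == "manual":
                fh.write(f"{json.dumps(name)}: {json.dumps(code)}\n")

    _write_tsv(paths["known_indications"], ["drug", "disease"],
               [[d, s] for d, s in known_indications])
    _write_tsv(paths["vip_pairs"], ["key1", "key2"],
               [[min(a, b), max(a, b)] for a, b in vip_pairs])

    truth.to_json(paths["ground_truth"])
    return paths, truth


def load_config_yaml(path) -> GeneratorConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: generator config must be a mapping")
    try:
        return GeneratorConfig(**data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from None
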