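# cpn — a cancer pharmacogenomics network for drug repurposing

`cpn` builds a **cancer-based pharmacogenomics (PGx) network**: a
heterogeneous graph whose nodes are drugs, diseases, genes, SNPs and
haplotypes, and whose edges are PGx associations integrated from three
kinds of resources — a PharmGKB-style relationships file, the GWAS
Catalog, and the FDA table of pharmacogenomic biomarkers in drug
labeling — with literature evidence attached from a SemMedDB-style
table of semantic predications. On top of the assembled network it
performs **path-based indication inference**: candidate new indications
for a query drug are the disease nodes within a bounded graph distance,
ranked by their best supporting path.

It is written for computational pharmacologists and biomedical
informaticians who want a reproducible, desk-scale implementation of
this construction, exercisable end-to-end on synthetic emulations of
the source formats with full ground truth.

## The method

1. **Seed expansion with degree weights.** Starting from a list of
   cancer terms (the *seeds*), the undirected association graph of the
   relationships file is searched breadth-first. A concept's *degree*
   is its minimal edge distance from any seed; the search stops after
   the fourth degree. Each retained concept gets a weight score
   `w = 5 − degree`: first-degree concepts score 4, second-degree 3,
   third-degree 2, fourth-degree 1 (seeds themselves carry degree 0,
   weight 5), encoding the assumption that seed-proximal concepts are
   more strongly cancer-associated.
2. **Co-occurrence restriction.** GWAS Catalog records are reduced to
   seed traits and split into disease–gene, disease–SNP and gene–SNP
   pairs; only pairs co-occurring with the PharmGKB expansion are kept.
   FDA rows whose therapeutic area is Oncology contribute drug–gene
   pairs.
3. **Normalization.** Diseases map to SNOMED-CT and drugs to RxNorm by
   a three-tier strategy — source-provided codes, then an exact-match
   terminology resolver (a packaged flat lexicon by default), then
   manual overrides; genes and SNPs are already standard (HGNC symbols,
   dbSNP rsIDs). Unmapped concepts stay in the network, tagged with a
   failure category (chemical IUPAC name, drug class, too broad/narrow).
4. **Evidence.** Subject–predicate–object predications decorate
   matching edges with their PubMed ids and predicates.
5. **Assembly and inference.** Nodes are merged across resources by
   normalized code, edges validated against a per-source matrix of
   allowed pair types, and the network exported as GraphML/SIF/TSV.
   For a query drug, every disease within radius 3 (edge distance) is a
   repurposing candidate, ranked by `(path length ↑, Σ node weights ↓,
   VIP-pair count ↓)` and flagged *novel* when absent from the drug's
   known-indication list.

## Worked example

The packaged fixture contains four association pairs forming a chain
away from the seed `Urinary bladder neoplasms`:

```bash
$ python analysis/01_worked_example.py
degree 0  weight 5  Urinary bladder neoplasms (disease)
degree 1  weight 4  rs762551 (variant)
degree 2  weight 3  Arthritis, Rheumatoid (disease)
degree 3  weight 2  CYP1A2 (gene)
degree 4  weight 1  olanzapine (drug)
```

Reading: the SNP rs762551 is directly associated with the seed (first
degree, weight 4); rheumatoid arthritis shares that SNP (second
degree); CYP1A2 is associated with rheumatoid arthritis (third degree);
and olanzapine, a CYP1A2 substrate, sits at the fourth degree with the
minimal weight 1 — the point at which the iterative search terminates.

The remaining drivers run the full pipeline on a synthetic bundle:

```bash
python analysis/02_generate_sources.py   # emit the five source files + truth
python analysis/03_build_network.py      # parse/expand/normalize/assemble
python analysis/04_repurpose.py          # rank disease candidates per drug
```

`analysis/04_repurpose.py` prints, for each planted query drug, its
neighbourhood profile and ranked candidates, e.g.

```
DRUG_004:
  2 concepts (0 diseases) at distance 1
  2 concepts (2 diseases) at distance 2
  candidate: Disease_001  distance=2  paths=1  [known]
  candidate: Disease_008  distance=2  paths=1  [novel]
```

— the planted drug→gene→disease path is recovered at distance 2 and the
disease not on the drug's label is flagged as the repurposing candidate.

A `cpn` console command exposes the same stages
(`synth`, `parse`, `expand`, `normalize`, `evidence`, `build`,
`repurpose`, `run`); see `cpn --help`.

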