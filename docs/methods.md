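# Methods

## Model

The package treats pharmacogenomic knowledge integration as the
construction of an undirected, typed, attributed graph. Nodes are
concepts of five types — drug, disease, gene, variant (SNP), haplotype
— and edges are association claims carried by one or more of three
resources (`pharmgkb`, `gwas`, `fda`). The construction is not a
statistical model: there is no likelihood and no fitting. Its
scientific content lies in four procedural commitments, each of which
is a tunable here:

1. **Degree-limited seed expansion.** Concept relevance to cancer is
   operationalized as graph proximity to a seed set of cancer terms.
   Degree is the *minimum* edge distance from any seed (the sources
   never state how to treat concepts reachable at several depths;
   minimum is the only choice consistent with "closer means stronger").
   The search is capped at `max_degree = 4` and each non-seed concept
   receives the node weight `5 − degree` (4/3/2/1). Seeds get degree 0
   and continue the line at weight 5; nothing downstream depends on the
   seed weight except path weight sums, where it uniformly benefits
   seed-containing paths. Seeds that match no concept in the
   relationships file are logged and omitted — they cannot be typed or
   connected, and keeping them would only pad the node count.
2. **Cross-resource restriction.** The GWAS Catalog is not expanded
   iteratively; records are reduced to seed traits and their pairs are
   kept only when at least one endpoint (`mode="any"`, configurable to
   `"both"`) already occurs in the PharmGKB expansion. The FDA table
   contributes Oncology drug–gene pairs unconditionally.
3. **Exact-match normalization.** Disease→SNOMED-CT and drug→RxNorm
   mapping tries three tiers in a fixed order: codes already present in
   the entity files, an exact-match resolver, then manual overrides.
   The resolver is an interface; the default implementation is a flat
   lexicon file, and the exact-match contract (case-insensitive,
   whitespace-collapsed, preferred names and synonyms only — no fuzzy
   matching) is what makes tier-2 mappings trustworthy without manual
   review. Unmapped concepts stay in the network with
   `method=unmapped` and a failure category assigned by ordered regex
   rules (chemical IUPAC name, drug class, too broad, too narrow,
   other); the rules are configurable because these categories are
   descriptive, not exhaustive.
4. **Bounded-path inference.** A repurposing candidate is a disease
   node within `radius = 3` *edges* of the query drug. "Three nodes
   away" admits two readings (edge count vs intermediate-node count);
   the edge-distance reading is adopted because the canonical
   drug–gene–disease and drug–gene/SNP–disease patterns have 2 and 3
   edges respectively. Candidates are ranked by the tuple (shortest
   path length ascending, path weight sum descending, VIP-edge count
   descending, disease key) — a total preorder made total by the
   lexicographic tail, so output order is deterministic. Only simple
   paths count, enumerated up to the radius and capped at
   `max_paths_per_disease` (default 25) after best-first sorting; the
   enumeration itself is bounded at 50× the cap to keep dense
   neighbourhoods tractable.

## Concept identity

Within one resource, a concept is identified by
`(ctype, casefolded-trimmed name)`. Across resources, nodes merge on
the normalized vocabulary code when one exists (`RxNorm:56946`),
otherwise on the typed name key. A name observed with two different
types in one source table is an integration error rather than a silent
split, because every downstream count depends on identity.

## Pair-type matrix

Each edge's pair type (e.g. `disease-snp`, labels ordered drug <
disease < gene < snp < haplotype) must be allowed for each source that
asserts it. Defaults: PharmGKB {disease-gene, disease-haplotype,
disease-snp, drug-gene, drug-haplotype, drug-snp, drug-drug,
gene-gene}, GWAS {disease-gene, disease-snp, gene-snp}, FDA
{drug-gene}. The PharmGKB set covers the eight pair types that a
seed-anchored extraction from the relationship format actually
produces (every pair involves a disease, drug or gene endpoint; the
disease–drug and gene–SNP combinations do not occur as direct rows).
Because which pair types a given snapshot of each resource asserts is
an empirical question rather than a fixed contract, the matrix is a
constructor argument, and a permissive mode downgrades violations to
warnings instead of failing the build.

## Synthetic data

`cpn.synth.generate_bundle` emits the five source files, the seed
list, lexicon, overrides, known indications and one VIP flag, plus a
`GroundTruth` record of every planted fact. It emulates:

* seed chains `disease–SNP–disease–gene–drug` (degrees 1–4), matching
  the worked-example pattern, with optional haplotype attachments and
  optional tails extended past the degree cap;
* planted repurposing paths `seed–gene–drug–gene–disease`, so the query
  drug reaches a novel disease and its known indication both at
  distance 2;
* cross-resource overlap (GWAS/FDA rows reusing planted genes, SNPs
  and drugs with probability `cross_resource_overlap`), trait-case
  jitter to exercise case-insensitive seed matching, a non-Oncology
  FDA decoy row, and predications covering a fraction
  `evidence_fraction` of the GWAS/FDA pairs, drawn from the predicate
  inventories observed for each resource;
* deliberately unmappable drug names (IUPAC-like and class-like) at
  rate `unmapped_fraction`.

Defaults (3 seeds, 4 chains, 2 repurposing paths, 1 beyond-cap tail,
4 GWAS and 3 FDA records, overlap 0.5, evidence 0.5, unmapped 0.15)
give a bundle of roughly 40 nodes — large enough that every planted
mechanism occurs, small enough that any discrepancy against ground
truth is inspectable by eye. Identical config and seed produce
byte-identical files; names are drawn from disjoint per-type alphabets
so identity collisions cannot arise by accident.

What the generator does **not** emulate: realistic degree
distributions, hub genes, term polysemy (one name, two types),
UMLS-style synonymy beyond the lexicon's synonym column, or noisy
predicate extraction. Passing the recovery tests therefore shows that
the pipeline's bookkeeping is exact under clean inputs, not that it is
robust to the ambiguity of the real resources — on real downloads the
normalization coverage and evidence yield would be dominated by
terminology quality, as the failure categories anticipate.

## Numerical and procedural choices

* Multi-valued cells split on both `,` and `;`; placeholder names
  (`NR`, `intergenic`, empty) are dropped and counted; curly quotes
  are normalized to ASCII on read; encoding is UTF-8.
* Self-loop rows are dropped (annotation rows in the relationship
  format can repeat an entity on both sides).
* PMID cells are split on `;`, keeping digit-only tokens.
* SNP ids must match `rs\d+`; anything else is skipped with a warning.
* Degree assignment is invariant to row order and to swapping the two
  entity columns (the graph is undirected); this is property-tested
  and independently checked against a hand-written Floyd–Warshall
  oracle.
* Coverage percentages are reported to one decimal
  (`round(100·mapped/total, 1)`).
* Manual override codes must be numeric (RxCUI / SNOMED-CT id syntax);
  violations are configuration errors raised before any mapping.
* GraphML is the canonical attribute-preserving export (set-valued
  attributes serialized as sorted `;`-joined strings and restored on
  import); SIF is attribute-free by design of the format.

## Scale

All tests and the acceptance script run at desk scale: random oracle
graphs up to 60 nodes, 20 generated bundles of ~40 nodes, and the
packaged four-pair worked example. These sizes were chosen so the
whole verification cycle completes in seconds while still exercising
every code path; the pipeline itself has no intrinsic size limit
beyond memory (the expansion and path enumeration are the usual
BFS/DFS complexities).

## Known limitations

* Evidence matching is by name, not by UMLS CUI; predications whose
  surface forms differ from every concept name (and every lexicon
  synonym) are invisible to it.
* The resolver ships as a lexicon; a live ontology-service client can
  implement the same interface but is deliberately not required
  anywhere.
* Indication vs adverse-event polarity of drug–disease edges is not
  disambiguated; predicates (including `NEG_` forms) are recorded
  verbatim and not interpreted.
* Path ranking is ordinal; no PageRank- or p-value-weighted scoring is
  provided.
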