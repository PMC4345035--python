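#!/usr/bin/env python
"""Build the cancer PGx network from the generated bundle.

Runs the full pipeline (parse -> expand -> co-occurrence filter ->
normalize -> evidence -> assemble) and reports the stage counters,
mapping coverage and network composition.  Outputs (GraphML, SIF,
node/edge TSVs, mapping report, manifest) land under results/cpn/.
"""

import json
from pathlib import Path

from cpn.pipeline import PipelineConfig, run_pipeline
from cpn.synth import GroundTruth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = RESULTS / "bundle"
    if not bundle.exists():
        raise SystemExit("run analysis/02_generate_sources.py first")
    truth = GroundTruth.from_json(bundle / "ground_truth.json")
    config = PipelineConfig(
        relationships=str(bundle / "pharmgkb_relationships.tsv"),
        entities=str(bundle / "pharmgkb_entities.tsv"),
        gwas=str(bundle / "gwas_catalog.tsv"),
        fda=str(bundle / "fda_biomarkers.tsv"),
        predications=str(bundle / "predications.tsv"),
        seeds=str(bundle / "seeds.txt"),
        lexicon=str(bundle / "lexicon.tsv"),
        overrides=str(bundle / "overrides.yaml"),
        known_indications=str(bundle / "known_indications.tsv"),
        vip_pairs=str(bundle / "vip_pairs.tsv"),
        outdir=str(RESULTS / "cpn"),
        query_drugs=tuple(truth.query_drugs))
    result = run_pipeline(config)

    stats = result.cpn.stats()
    print("network composition:")
    print(json.dumps(stats, indent=2, sort_keys=True))
    print("\nmapping coverage:")
    for line in result.report.summary_lines():
        print(" ", line)
    recovered = {k: r.degree for k, r in result.expansion.degrees.items()}
    print(f"\nplanted degrees recovered exactly: "
          f"{recovered == truth.degrees}")
    print(f"outputs under {RESULTS / 'cpn'}")


if __name__ == "__main__":
    main()
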