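#!/usr/bin/env python
"""Generate the synthetic source bundle used by the downstream steps.

Emulates the five resource formats (PharmGKB relationships + entity
files, GWAS Catalog, FDA biomarker table, SemMedDB predications) with
planted seed chains, cross-resource overlaps and repurposing paths,
and records every planted fact in ground_truth.json.
"""

import json
from pathlib import Path

from cpn.synth import GeneratorConfig, generate_bundle

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = GeneratorConfig(rng_seed=2026)
    paths, truth = generate_bundle(config, RESULTS / "bundle")
    print(f"bundle written under {RESULTS / 'bundle'}")
    print(f"  planted concepts within the degree cap: {len(truth.degrees)}")
    print(f"  planted pairs: {len(truth.pairs)}")
    print(f"  planted repurposing facts: "
          f"{json.dumps(truth.repurposing, indent=2)}")


if __name__ == "__main__":
    main()
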