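#!/usr/bin/env python
"""Worked example: degree-weighted expansion of the printed pair chain.

The four packaged example associations form a chain from the cancer
seed "Urinary bladder neoplasms" to the antipsychotic olanzapine.
Expanding from the seed assigns each concept its distance-based weight
score; the table written to results/worked_example.tsv should show
rs762551 at degree 1 / weight 4 down to olanzapine at degree 4 /
weight 1.
"""

import csv
from pathlib import Path

from cpn import sources as src
from cpn.expansion import expand_from_seeds

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rel, seeds = src.packaged_example()
    rows = src.read_pharmgkb_relationships(rel).rows
    result = expand_from_seeds(rows, src.read_seed_list(seeds), max_degree=4)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "worked_example.tsv"
    with open(out, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "ctype", "degree", "weight"])
        for key, rec in sorted(result.degrees.items(),
                               key=lambda kv: kv[1].degree):
            c = result.concepts[key]
            w.writerow([c.name, c.ctype, rec.degree, rec.weight])
            print(f"degree {rec.degree}  weight {rec.weight}  "
                  f"{c.name} ({c.ctype})")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
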