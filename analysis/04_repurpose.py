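#!/usr/bin/env python
"""Indication inference for the planted query drugs.

Loads the assembled network, profiles each query drug's neighbourhood
(distinct concepts and diseases at exact distances 1..3), and ranks
the disease candidates within the default radius, flagging those not
on the drug's known-indication list as novel.  Candidate tables are
the candidates_<drug>.tsv files already written by the pipeline; this
step re-derives them from the exported GraphML to demonstrate the
round trip and writes a combined summary.
"""

import csv
from pathlib import Path

from cpn.network import load_graphml
from cpn.repurposing import (
    degree_profile,
    infer_indications,
    load_known_indications,
)
from cpn.synth import GroundTruth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    graphml = RESULTS / "cpn" / "cpn.graphml"
    if not graphml.exists():
        raise SystemExit("run analysis/03_build_network.py first")
    cpn = load_graphml(graphml)
    truth = GroundTruth.from_json(RESULTS / "bundle" / "ground_truth.json")
    known = load_known_indications(RESULTS / "bundle" / "known_indications.tsv",
                                   cpn)

    out = RESULTS / "repurposing_summary.tsv"
    with open(out, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["drug", "disease", "distance", "n_paths",
                    "shortest_path", "novel"])
        for drug in truth.query_drugs:
            node = cpn.require_node(drug)
            profile = degree_profile(cpn, node, 3)
            print(f"\n{drug}:")
            for dist, (total, diseases) in profile.items():
                print(f"  {total} concepts ({diseases} diseases) at "
                      f"distance {dist}")
            for c in infer_indications(cpn, node, radius=3,
                                       known=known.get(node, set())):
                name = cpn.graph.nodes[c.disease]["name"]
                tag = "novel" if c.novel else "known"
                print(f"  candidate: {name}  distance={c.distance}  "
                      f"paths={len(c.paths)}  [{tag}]")
                w.writerow([drug, name, c.distance, len(c.paths),
                            ">".join(c.shortest.nodes), int(c.novel)])
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
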