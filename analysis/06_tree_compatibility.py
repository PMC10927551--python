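#!/usr/bin/env python
"""Gene-tree 1R/2R compatibility under increasing topology error.

True gene-family trees are transcribed from a history with an outgroup, a
pre-WGD lineage, a post-1R ("cyclostome-like") lineage, a post-2R
("shark-like") lineage and two reference genomes, with modest gene loss.
Test genes are classified against the ((A,B),(C,D)) backbone; random NNI
perturbations then erode the support fractions, mimicking gene-tree
estimation error.
"""

import json
from pathlib import Path

from paleokaryo.simulate import (
    EvolutionScenario,
    backbone_pairing,
    run_scenario,
    simulate_gene_trees,
)
from paleokaryo.treecompat import classify_test_genes, label_backbone, tally_support

OUT = Path(__file__).resolve().parent.parent / "results"


def build_result(seed: int = 7):
    scenario = EvolutionScenario(
        6, 80,
        [
            {"type": "branch", "name": "out", "loss_rate": 0.05},
            {"type": "branch", "name": "pre1r", "loss_rate": 0.1},
            {"type": "wgd", "multiplicity": 2},
            {"type": "attrition", "loss_rate": 0.1},
            {"type": "branch", "name": "cyclo", "loss_rate": 0.15},
            {"type": "wgd", "multiplicity": 2},
            {"type": "attrition", "loss_rate": 0.15},
            {"type": "branch", "name": "shark", "loss_rate": 0.1},
            {"type": "speciate", "names": ["gar", "chicken"], "loss_rate": 0.1},
        ],
        seed=seed,
    )
    return run_scenario(scenario)


def classify_all(result, error_rate: float, seed: int = 0):
    trees = simulate_gene_trees(result, seed=seed, error_rate=error_rate)
    calls, unusable = [], 0
    for fam, nwk in sorted(trees.items()):
        pairing = backbone_pairing(result, "gar", fam.split("g")[0])
        try:
            t = label_backbone(nwk, pairing, {"gar", "chicken"}, {"out"}, fam)
        except ValueError:
            unusable += 1
            continue
        if not t.usable:
            unusable += 1
            continue
        calls.extend(classify_test_genes(t, {"shark", "cyclo", "pre1r"}))
    return tally_support(calls, per_tree=True), unusable


def main() -> None:
    result = build_result()
    report = {}
    for e in (0.0, 0.1, 0.3):
        table, unusable = classify_all(result, e)
        report[f"error_{e}"] = {
            "unusable_trees": unusable,
            **{
                row.test_species: {
                    "n": int(row.n),
                    "frac_1R": round(float(row.frac_1R), 3),
                    "frac_2R": round(float(row.frac_2R), 3),
                }
                for row in table.itertuples(index=False)
            },
        }
        print(f"NNI error rate {e}:")
        for sp, vals in report[f"error_{e}"].items():
            if sp != "unusable_trees":
                print(
                    f"  {sp:6s} n={vals['n']:3d}  1R {vals['frac_1R']:.3f}  "
                    f"2R {vals['frac_2R']:.3f}"
                )
    OUT.mkdir(exist_ok=True)
    (OUT / "tree_compatibility.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
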