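#!/usr/bin/env python
"""Prognostic value of module activity (mean-dichotomized KM + log-rank,
direction consistency) and druggability of the full architecture."""

import argparse
from pathlib import Path

import pandas as pd

from matrisome_atlas import direction_consistency, io, map_druggability, survival_scan
from matrisome_atlas.simulate import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    expr = io.read_expression(args.dir / "expression.tsv")
    annot = io.read_table(args.dir / "annotations.tsv")
    modules = io.read_table(args.dir / "modules.tsv")
    masters = io.read_table(args.dir / "masters.tsv")
    signatures = io.read_table(args.dir / "signatures.tsv")
    drugs = io.load_drug_table(args.dir / "drugs.tsv")
    truth = GroundTruth.from_json(args.dir / "ground_truth.json")

    final = modules[modules["final"]]
    survival_tables, drug_tables = [], []
    for tumor in truth.tumor_types:
        pairs = list(
            final.loc[final["tumor"] == tumor, ["tf", "target"]].itertuples(index=False)
        )
        table = survival_scan(expr, annot, [(p.tf, p.target) for p in pairs], tumor)
        survival_tables.append(table)
        sig = (table["p"] < 0.05).sum()
        planted = {pair: d for pair, d in truth.planted_prognostic[tumor]}
        recovered = sum(
            1
            for r in table.itertuples(index=False)
            if (r.tf, r.target) in planted
            and r.p < 0.05
            and r.direction == planted[(r.tf, r.target)]
        )
        print(f"{tumor}: {sig}/{len(table)} modules prognostic at P < 0.05; "
              f"{recovered}/{len(planted)} planted effects recovered with direction")
        violations = direction_consistency(table)
        if violations:
            print(f"  direction-consistency violations: {violations}")

        architecture = {
            "matrisome": set(signatures.loc[signatures["tumor_type"] == tumor, "gene"]),
            "TF": set(final.loc[final["tumor"] == tumor, "tf"]),
            "master": set(masters.loc[masters["tumor_type"] == tumor, "driver"]),
        }
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # off-architecture drug targets
            report = map_druggability(architecture, drugs, tumor)
        report.insert(0, "tumor_type", tumor)
        drug_tables.append(report)

    io.write_table(pd.concat(survival_tables, ignore_index=True), args.dir / "survival.tsv")
    druggability = pd.concat(drug_tables, ignore_index=True)
    io.write_table(druggability, args.dir / "druggability.tsv")
    by_layer = druggability.groupby("layer")["drug"].count()
    on_label = (druggability["label_status"] == "on-label").sum()
    print(f"druggability: {len(druggability)} drug-gene rows "
          f"({dict(by_layer)}), {on_label} on-label")


if __name__ == "__main__":
    main()
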