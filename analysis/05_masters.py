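#!/usr/bin/env python
"""Master-regulator layer: frequency + PPI-coverage filters, cross-tumor
summary, cluster-level regulator extraction (linear SVM + ROC AUC), and
pathway over-representation with mutational-activation flags."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from matrisome_atlas import (
    cluster_regulator_selection,
    find_masters,
    io,
    pathway_enrichment,
    regulator_summary,
)
from matrisome_atlas.simulate import GroundTruth


def synthetic_pathway_table(truth: GroundTruth, universe: list[str], seed: int):
    """A synthetic GMT-style pathway table: per-tumor regulatory pathways
    (masters + module TFs) plus random background pathways."""
    rng = np.random.default_rng(seed)
    pathways = {}
    for tumor in truth.tumor_types:
        pathways[f"pw_regulation_{tumor}"] = (
            truth.planted_masters[tumor] | truth.module_tfs(tumor)
        )
    for i in range(10):
        pathways[f"pw_background_{i:02d}"] = set(
            rng.choice(universe, size=15, replace=False)
        )
    return pathways


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    expr = io.read_expression(args.dir / "expression.tsv")
    annot = io.read_table(args.dir / "annotations.tsv")
    drivers = io.read_table(args.dir / "drivers.tsv")
    ppi = io.read_table(args.dir / "ppi.tsv")
    modules = io.read_table(args.dir / "modules.tsv")
    clusters = dict(io.read_table(args.dir / "tumor_clusters.tsv").itertuples(index=False))
    truth = GroundTruth.from_json(args.dir / "ground_truth.json")

    final = modules[modules["final"]]
    masters_per_tumor, rows = {}, []
    for tumor in truth.tumor_types:
        tfs = set(final.loc[final["tumor"] == tumor, "tf"])
        masters = find_masters(drivers, ppi, tfs, tumor) if tfs else []
        masters_per_tumor[tumor] = masters
        for m in masters:
            rows.append(
                {
                    "tumor_type": tumor,
                    "driver": m.driver,
                    "driver_class": m.driver_class,
                    "coverage": m.coverage,
                    "tf_partners": ";".join(sorted(m.tf_partners)),
                }
            )
    io.write_table(pd.DataFrame(rows), args.dir / "masters.tsv")

    summary = regulator_summary(masters_per_tumor)
    print(f"masters per tumor: mean {summary['mean_total']:.1f} total, "
          f"{summary['mean_specific']:.1f} tumor-specific; "
          f"weighted avg TFs per master {summary['weighted_avg_tfs_per_master']:.2f}")
    print(f"common regulators (>= 2 tumors): {summary['common_regulators'] or 'none'}")

    by_cluster: dict[int, set] = {}
    for tumor, c in clusters.items():
        by_cluster.setdefault(c, set()).add(tumor)
    multi = {c: m for c, m in by_cluster.items() if len(m) >= 2}
    if not multi:
        # fall back to the pair of tumors sharing the planted common master
        shared = [t for t in truth.tumor_types
                  if any(truth.master_classes[g] == "pan-cancer"
                         for g in truth.planted_masters[t])]
        if len(shared) >= 2:
            multi = {0: set(shared[:2])}
    sel_rows = []
    for c, members in sorted(multi.items()):
        sel = cluster_regulator_selection(
            masters_per_tumor, expr, annot, members, seed=args.seed
        )
        for g in sel["regulators"]:
            sel_rows.append(
                {
                    "cluster": c,
                    "members": ";".join(sorted(members)),
                    "regulator": g,
                    "importance": sel["importances"][g],
                    "auc": sel["auc"],
                }
            )
        print(f"cluster {sorted(members)}: shared regulators "
              f"{sel['regulators'] or 'none'}, AUC {sel['auc']:.3f}")
    io.write_table(
        pd.DataFrame(sel_rows, columns=["cluster", "members", "regulator", "importance", "auc"]),
        args.dir / "cluster_regulators.tsv",
    )

    universe = sorted(expr.index)
    pathways = synthetic_pathway_table(truth, universe, args.seed)
    io.write_gmt(pathways, args.dir / "pathways_synthetic.gmt")
    enrich_rows = []
    for tumor in truth.tumor_types:
        regulatory = {m.driver for m in masters_per_tumor[tumor]} | set(
            final.loc[final["tumor"] == tumor, "tf"]
        )
        if not regulatory:
            continue
        specific = {
            m.driver for m in masters_per_tumor[tumor] if m.driver_class == "tumor-specific"
        }
        table = pathway_enrichment(regulatory, pathways, set(universe), specific)
        table.insert(0, "tumor_type", tumor)
        enrich_rows.append(table)
        top = table.sort_values("fdr").iloc[0]
        print(f"{tumor}: top pathway {top['pathway']} (FDR {top['fdr']:.2g}, "
              f"mutationally activated: {bool(top['mutationally_activated'])})")
    io.write_table(pd.concat(enrich_rows, ignore_index=True), args.dir / "pathway_enrichment.tsv")


if __name__ == "__main__":
    main()
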