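#!/usr/bin/env python
"""Per-tumor matrisome signatures (up vs matched healthy AND vs the rest
of the cohort) and cluster-level signatures by intersection."""

import argparse
from pathlib import Path

import pandas as pd

from matrisome_atlas import infer_all_signatures, infer_cluster_signature, io
from matrisome_atlas import signature_composition_test
from matrisome_atlas.simulate import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    expr = io.read_expression(args.dir / "expression.tsv")
    annot = io.read_table(args.dir / "annotations.tsv")
    catalog = io.read_table(args.dir / "matrisome_catalog.tsv")
    clusters = dict(
        io.read_table(args.dir / "tumor_clusters.tsv").itertuples(index=False)
    )
    truth = GroundTruth.from_json(args.dir / "ground_truth.json")

    signatures = infer_all_signatures(expr, annot, catalog, clusters=clusters)
    rows = []
    cat = catalog.set_index("gene_id")["category"]
    for tumor, sig in sorted(signatures.items()):
        members = sig.table[sig.table["member"]]
        for r in members.itertuples(index=False):
            rows.append(
                {
                    "tumor_type": tumor,
                    "gene": r.gene,
                    "category": cat[r.gene],
                    "p_adj_vs_healthy": r.p_adj_vs_healthy,
                    "p_adj_vs_rest": r.p_adj_vs_rest,
                }
            )
        planted = truth.planted_signatures[tumor]
        print(f"{tumor}: {len(sig.genes)} signature genes "
              f"({len(sig.genes & planted)}/{len(planted)} planted recovered)")
    io.write_table(pd.DataFrame(rows), args.dir / "signatures.tsv")

    try:
        stat, p, _ = signature_composition_test(signatures, catalog)
        print(f"composition contingency across matrisome categories: "
              f"chi-square {stat:.1f} (P = {p:.2g})")
    except ValueError as exc:
        print(f"composition contingency skipped: {exc}")

    cluster_rows = []
    by_cluster: dict[int, set] = {}
    for tumor, c in clusters.items():
        by_cluster.setdefault(c, set()).add(tumor)
    for c, members in sorted(by_cluster.items()):
        if len(members) < 2:
            continue
        shared = infer_cluster_signature(signatures, members)
        for g in sorted(shared):
            cluster_rows.append({"cluster": c, "gene": g})
        print(f"cluster {c} ({', '.join(sorted(members))}): {len(shared)} shared genes")
    io.write_table(
        pd.DataFrame(cluster_rows, columns=["cluster", "gene"]),
        args.dir / "cluster_signatures.tsv",
    )


if __name__ == "__main__":
    main()
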