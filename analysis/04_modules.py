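#!/usr/bin/env python
"""Consensus TF->target module inference per tumor, with staining
cross-validation and recovery scoring against the planted truth."""

import argparse
from pathlib import Path

import pandas as pd

from matrisome_atlas import io, run_module_pipeline, staining_crossval
from matrisome_atlas.simulate import GroundTruth


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--dir", type=Path, default=Path("results/run"))
    args = parser.parse_args()

    expr = io.read_expression(args.dir / "expression.tsv")
    annot = io.read_table(args.dir / "annotations.tsv")
    priors = io.read_table(args.dir / "priors.tsv")
    staining = io.read_table(args.dir / "staining.tsv")
    signatures = io.read_table(args.dir / "signatures.tsv")
    truth = GroundTruth.from_json(args.dir / "ground_truth.json")

    all_modules, count_rows = [], []
    tp = fp = fn = 0
    for tumor in truth.tumor_types:
        sig_genes = set(signatures.loc[signatures["tumor_type"] == tumor, "gene"])
        res = run_module_pipeline(expr, annot, priors, sig_genes, tumor, seed=args.seed)
        all_modules.append(res.modules)
        count_rows.append({"tumor_type": tumor, **res.counts})
        final = res.final_pairs()
        planted = truth.planted_modules[tumor]
        tp += len(final & planted)
        fp += len(final - planted)
        fn += len(planted - final)
        print(f"{tumor}: {res.counts['mined']} mined -> "
              f"{res.counts['post_correlation']} after correlation -> "
              f"{res.counts['post_youden']} after Youden -> "
              f"{res.counts['model1']} model 1 -> {res.counts['final']} final "
              f"(threshold zCor > {res.threshold.threshold:.2f})")
    modules = pd.concat(all_modules, ignore_index=True)
    io.write_table(modules, args.dir / "modules.tsv")
    io.write_table(pd.DataFrame(count_rows), args.dir / "module_stage_counts.tsv")
    print(f"recovery vs planted truth: precision {tp / max(tp + fp, 1):.3f}, "
          f"recall {tp / max(tp + fn, 1):.3f}")

    final = modules[modules["final"]]
    proteins = sorted(set(final["tf"]) | set(final["target"]))
    validation = staining_crossval(proteins, staining)
    io.write_table(validation, args.dir / "staining_validation.tsv")
    assayed = validation[validation["assayed"]]
    print(f"staining cross-validation: {int(assayed['validated'].sum())}/{len(assayed)} "
          f"assayed proteins with PPS > 0 "
          f"(mean PPS {assayed['pps'].mean():.1f}%)")


if __name__ == "__main__":
    main()
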