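#!/usr/bin/env python
"""Generate one synthetic pan-tumor study and write every input table.

Emulates the inputs of a pan-cancer matrisome analysis: log2-scale
expression with matched healthy tissues, matrisome catalog, TF->target
priors from six evidence sources, driver mutation frequencies, PPI edges,
IHC staining, survival follow-up, and a drug-gene table — all with
planted ground truth stored alongside.
"""

import argparse
from pathlib import Path

from matrisome_atlas import SimConfig, io
from matrisome_atlas.simulate import generate_all


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/run"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(seed=args.seed)
    data = generate_all(config)

    io.write_expression(data["expr"], args.out / "expression.tsv")
    io.write_table(data["annot"], args.out / "annotations.tsv")
    io.write_table(data["catalog"], args.out / "matrisome_catalog.tsv")
    io.write_table(data["priors"], args.out / "priors.tsv")
    io.write_table(data["drivers"], args.out / "drivers.tsv")
    io.write_table(data["ppi"], args.out / "ppi.tsv")
    io.write_table(data["staining"], args.out / "staining.tsv")
    io.write_table(data["drugs"], args.out / "drugs.tsv")
    data["truth"].to_json(args.out / "ground_truth.json")

    n_tumor = (data["annot"]["sample_class"] != "healthy").sum()
    n_planted = sum(len(m) for m in data["truth"].planted_modules.values())
    print(f"cohort: {data['expr'].shape[0]} genes x {data['expr'].shape[1]} samples "
          f"({n_tumor} tumor) across {config.n_tumor_types} tumor types")
    print(f"planted: {n_planted} modules, "
          f"{sum(len(s) for s in data['truth'].planted_signatures.values())} signature genes, "
          f"{len(set().union(*data['truth'].planted_masters.values()))} master regulators")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
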