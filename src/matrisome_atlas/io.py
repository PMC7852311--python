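"""Plain-text readers/writers for the study tables (TSV + JSON sidecars)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def load_drug_table(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load drug-gene interactions, dropping rows without a mechanism.

    Mechanism-less entries never enter the pipeline; they are removed here,
    at load time.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", keep_default_na=False)
    mech = df["mechanism"].fillna("").astype(str).str.strip()
    return df.loc[mech != ""].reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT pathway file: name <tab> description <tab> genes..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        pathways[fields[0]] = set(fields[2:])
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)]) for name, genes in sorted(pathways.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
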