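"""Per-tumor matrisome signatures.

A signature gene must be up-regulated (positive difference of log2-scale
means) versus the tumor's matched healthy tissue AND versus the pooled
rest of the cohort (excluding same-cluster tumors), each comparison a
two-sided Welch t-test with Benjamini-Hochberg adjustment applied
separately within its own family (all matrisome genes, one tumor, one
comparison) at adjusted P < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class NoMatchedHealthyError(ValueError):
    """The tumor has no matched healthy samples; its signature is skipped."""


@dataclass
class Signature:
    tumor_type: str
    genes: set[str]
    table: pd.DataFrame  # gene, mean_tumor, mean_healthy, mean_rest, p_adj_vs_healthy, p_adj_vs_rest


def infer_signature(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    matrisome: pd.DataFrame,
    tumor: str,
    clusters: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> Signature:
    """Infer the matrisome signature of one tumor.

    ``clusters`` (tumor -> cluster label) removes same-cluster tumors from
    the rest-of-cohort comparison group, so tumors sharing a matrisome
    program do not mask each other's signatures.
    """
    genes = sorted(set(matrisome["gene_id"]) & set(expr.index))
    if not genes:
        raise ValueError("no matrisome gene found in the expression matrix")

    is_healthy = annot["sample_class"] == "healthy"
    tumor_samples = annot.loc[(annot["tumor_type"] == tumor) & ~is_healthy, "sample_id"]
    healthy_samples = annot.loc[(annot["tumor_type"] == tumor) & is_healthy, "sample_id"]
    if healthy_samples.empty:
        raise NoMatchedHealthyError(
            f"tumor {tumor} has no matched healthy tissue; signature skipped"
        )
    excluded = {tumor}
    if clusters is not None and tumor in clusters:
        excluded |= {t for t, c in clusters.items() if c == clusters[tumor]}
    rest_samples = annot.loc[~annot["tumor_type"].isin(excluded) & ~is_healthy, "sample_id"]
    for name, group in (
        ("tumor", tumor_samples),
        ("healthy", healthy_samples),
        ("rest-of-cohort", rest_samples),
    ):
        if len(group) < 2:
            raise ValueError(f"fewer than 2 samples in the {name} group for {tumor}")

    a = expr.loc[genes, tumor_samples].to_numpy()
    h = expr.loc[genes, healthy_samples].to_numpy()
    r = expr.loc[genes, rest_samples].to_numpy()

    with np.errstate(invalid="ignore"):
        p_h = stats.ttest_ind(a, h, axis=1, equal_var=False).pvalue
        p_r = stats.ttest_ind(a, r, axis=1, equal_var=False).pvalue
    p_h = np.nan_to_num(p_h, nan=1.0)  # constant gene in both groups -> no evidence
    p_r = np.nan_to_num(p_r, nan=1.0)
    p_adj_h = multipletests(p_h, method="fdr_bh")[1]
    p_adj_r = multipletests(p_r, method="fdr_bh")[1]

    mean_t, mean_h, mean_r = a.mean(axis=1), h.mean(axis=1), r.mean(axis=1)
    keep = (mean_t > mean_h) & (p_adj_h < alpha) & (mean_t > mean_r) & (p_adj_r < alpha)

    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_tumor": mean_t,
            "mean_healthy": mean_h,
            "mean_rest": mean_r,
            "p_raw_vs_healthy": p_h,
            "p_raw_vs_rest": p_r,
            "p_adj_vs_healthy": p_adj_h,
            "p_adj_vs_rest": p_adj_r,
            "member": keep,
        }
    )
    return Signature(
        tumor_type=tumor,
        genes=set(table.loc[keep, "gene"]),
        table=table,
    )


def infer_all_signatures(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    matrisome: pd.DataFrame,
    clusters: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> dict[str, Signature]:
    """Signatures for every tumor with matched healthy tissue; the rest are
    skipped with a logged reason."""
    out: dict[str, Signature] = {}
    tumors = sorted(annot.loc[annot["sample_class"] != "healthy", "tumor_type"].unique())
    for tumor in tumors:
        try:
            out[tumor] = infer_signature(expr, annot, matrisome, tumor, clusters, alpha)
        except NoMatchedHealthyError as exc:
            logger.info(str(exc))
    return out


def infer_cluster_signature(
    signatures: dict[str, Signature], members: set[str]
) -> set[str]:
    """Cluster signature: genes common to every member's signature."""
    present = [signatures[t] for t in sorted(members) if t in signatures]
    if len(present) < 2:
        raise ValueError("a cluster signature needs >= 2 member signatures")
    result = set(present[0].genes)
    for sig in present[1:]:
        result &= sig.genes
    return result


def signature_composition_test(
    signatures: dict[str, Signature], matrisome: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square contingency of signature composition by matrisome category.

    Builds the tumor x category member-count table and applies the shared
    contingency test (Yates-corrected when 2x2).
    """
    from .landscape import contingency_test

    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures")
    cat = matrisome.set_index("gene_id")["category"]
    rows = {}
    for tumor, sig in sorted(signatures.items()):
        rows[tumor] = cat.loc[sorted(sig.genes)].value_counts()
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    table = table.loc[:, table.sum(axis=0) > 0]
    stat, p = contingency_test(table.to_numpy())
    return stat, p, table
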