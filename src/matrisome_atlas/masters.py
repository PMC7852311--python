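"""Master-regulator layer above the module TFs.

A cancer driver becomes a "master regulator" of a tumor's matrisome when
it (a) passes a mutation-frequency filter — tumor-specific drivers need
in-tumor frequency strictly above 5%, pan-cancer drivers need in-tumor
frequency strictly above their own cross-cohort mean — and (b) physically
interacts (PPI) with strictly more than 10% of the tumor's module TFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

SPECIFIC_FREQ_CUTOFF = 0.05
COVERAGE_CUTOFF = 0.10


@dataclass
class MasterRegulator:
    driver: str
    tumor: str
    driver_class: str
    tf_partners: set[str]
    coverage: float


def filter_drivers(drivers: pd.DataFrame, tumor: str) -> pd.DataFrame:
    """Frequency filters, both strict.

    Tumor-specific drivers: in-tumor mutation frequency > 5%.
    Pan-cancer drivers: in-tumor frequency > the driver's mean frequency
    across all tumors where it is recorded.
    """
    rows = []
    specific = drivers[
        (drivers["driver_class"] == "tumor-specific") & (drivers["tumor_type"] == tumor)
    ]
    for row in specific.itertuples(index=False):
        if pd.isna(row.mutation_frequency):
            warnings.warn(f"driver {row.gene} missing frequency in {tumor}; skipped")
            continue
        if row.mutation_frequency > SPECIFIC_FREQ_CUTOFF:
            rows.append(
                {
                    "gene": row.gene,
                    "driver_class": "tumor-specific",
                    "frequency": row.mutation_frequency,
                }
            )
    pan = drivers[drivers["driver_class"] == "pan-cancer"]
    for gene, grp in pan.groupby("gene", sort=True):
        here = grp[grp["tumor_type"] == tumor]
        if here.empty or here["mutation_frequency"].isna().all():
            warnings.warn(f"pan-cancer driver {gene} missing frequency in {tumor}; skipped")
            continue
        freq = float(here["mutation_frequency"].iloc[0])
        if freq > float(grp["mutation_frequency"].mean()):
            rows.append({"gene": gene, "driver_class": "pan-cancer", "frequency": freq})
    return pd.DataFrame(rows, columns=["gene", "driver_class", "frequency"])


def link_masters(
    candidates: pd.DataFrame, ppi: pd.DataFrame, tumor_tfs: set[str], tumor: str
) -> list[MasterRegulator]:
    """Retain candidate drivers contacting > 10% of the tumor's module TFs."""
    if not tumor_tfs:
        raise ValueError("tumor_tfs must be non-empty")
    if ppi.empty:
        warnings.warn("empty PPI table: no master regulator can be linked")
        return []
    partners: dict[str, set[str]] = {}
    for a, b in zip(ppi["protein_a"], ppi["protein_b"]):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    masters = []
    for row in candidates.itertuples(index=False):
        linked = partners.get(row.gene, set()) & tumor_tfs
        coverage = len(linked) / len(tumor_tfs)
        if coverage > COVERAGE_CUTOFF:
            masters.append(
                MasterRegulator(
                    driver=row.gene,
                    tumor=tumor,
                    driver_class=row.driver_class,
                    tf_partners=linked,
                    coverage=coverage,
                )
            )
    return sorted(masters, key=lambda m: m.driver)


def find_masters(
    drivers: pd.DataFrame, ppi: pd.DataFrame, tumor_tfs: set[str], tumor: str
) -> list[MasterRegulator]:
    return link_masters(filter_drivers(drivers, tumor), ppi, tumor_tfs, tumor)


def regulator_summary(masters_per_tumor: dict[str, list[MasterRegulator]]) -> dict:
    """Counts and TF-per-master distribution across tumors.

    ``common`` regulators occur in >= 2 tumors; the weighted average of
    TFs per master pools every (master, tumor) occurrence.
    """
    per_tumor = {
        t: {
            "total": len(ms),
            "tumor_specific": sum(m.driver_class == "tumor-specific" for m in ms),
        }
        for t, ms in masters_per_tumor.items()
    }
    occurrences: dict[str, int] = {}
    partner_counts = []
    for ms in masters_per_tumor.values():
        for m in ms:
            occurrences[m.driver] = occurrences.get(m.driver, 0) + 1
            partner_counts.append(len(m.tf_partners))
    common = sorted(d for d, c in occurrences.items() if c >= 2)
    unique = sorted(d for d, c in occurrences.items() if c == 1)
    return {
        "per_tumor": per_tumor,
        "mean_total": float(np.mean([v["total"] for v in per_tumor.values()])) if per_tumor else 0.0,
        "mean_specific": (
            float(np.mean([v["tumor_specific"] for v in per_tumor.values()])) if per_tumor else 0.0
        ),
        "weighted_avg_tfs_per_master": (
            float(np.mean(partner_counts)) if partner_counts else float("nan")
        ),
        "common_regulators": common,
        "unique_regulators": unique,
    }


def cluster_regulator_selection(
    masters_per_tumor: dict[str, list[MasterRegulator]],
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    cluster: set[str],
    n_splits: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> dict:
    """Cluster-level regulator extraction with a linear margin classifier.

    Master lists are intersected across cluster members; the shared
    regulators' expression feeds an L2-penalized linear SVM separating
    cluster samples from the rest over ``n_splits`` random 80/20 splits.
    Returns the shared regulators, normalized predictor importances
    (mean |coefficient|), and the mean held-out ROC AUC.
    """
    members = sorted(cluster)
    if len(members) < 2:
        raise ValueError("cluster needs >= 2 members")
    shared: set[str] | None = None
    for t in members:
        genes = {m.driver for m in masters_per_tumor.get(t, [])}
        shared = genes if shared is None else shared & genes
    shared = shared or set()
    if not shared:
        warnings.warn("no master regulator shared by all cluster members")
        return {"regulators": [], "importances": {}, "auc": float("nan")}
    features = sorted(shared & set(expr.index))
    non_healthy = annot[annot["sample_class"] != "healthy"]
    X = expr.loc[features, non_healthy["sample_id"]].to_numpy().T
    y = non_healthy["tumor_type"].isin(cluster).to_numpy().astype(int)
    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=0.2, random_state=seed)
    aucs, coefs = [], []
    for tr, te in splitter.split(X, y):
        clf = make_pipeline(
            StandardScaler(), LinearSVC(penalty="l2", C=C, dual="auto", random_state=seed)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
        coefs.append(np.abs(clf.named_steps["linearsvc"].coef_.ravel()))
    mean_coef = np.mean(coefs, axis=0)
    total = mean_coef.sum()
    importances = {
        f: float(c / total) if total > 0 else 1.0 / len(features)
        for f, c in zip(features, mean_coef)
    }
    return {"regulators": features, "importances": importances, "auc": float(np.mean(aucs))}


def pathway_enrichment(
    regulatory_genes: set[str],
    pathway_table: dict[str, set[str]],
    universe: set[str],
    specific_masters: set[str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH FDR.

    A pathway is flagged mutationally activated when at least two
    cancer-specific master regulators (``specific_masters``) belong to it.
    """
    if not pathway_table:
        raise ValueError("pathway_table must be non-empty")
    outside = regulatory_genes - universe
    if outside:
        raise ValueError(f"genes outside the universe: {sorted(outside)[:5]}")
    specific_masters = specific_masters or set()
    M, N = len(universe), len(regulatory_genes)
    rows = []
    for name, genes in sorted(pathway_table.items()):
        in_universe = genes & universe
        overlap = len(in_universe & regulatory_genes)
        p = float(hypergeom.sf(overlap - 1, M, len(in_universe), N)) if overlap else 1.0
        n_specific = len(genes & specific_masters)
        rows.append(
            {
                "pathway": name,
                "overlap": overlap,
                "pathway_size": len(in_universe),
                "p_value": min(p, 1.0),
                "mutationally_activated": n_specific >= 2,
            }
        )
    result = pd.DataFrame(rows)
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result[["pathway", "overlap", "pathway_size", "p_value", "fdr", "mutationally_activated"]]
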