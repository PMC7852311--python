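"""Prognostic value of module activity, and druggability mapping.

Module activity is the per-sample mean of the TF's and target's log2
expression; each cohort is dichotomized at the cohort mean into high
(strictly above) vs low, and the strata are compared by Kaplan-Meier /
log-rank.  Direction comes from the restricted-mean observed survival of
the fitted KM curves: "noxious" when the high-activity stratum fares
worse.  Survival P values are reported raw (per-module monovariate tests),
with BH-adjusted values alongside for transparency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalResult:
    tf: str
    target: str
    tumor: str
    logrank_stat: float
    logrank_p: float
    direction: str | None  # defined only when logrank_p < 0.05
    n_high: int
    n_low: int


def module_activity(expr: pd.DataFrame, tf: str, target: str) -> pd.Series:
    """Per-sample mean of the TF and target expression values."""
    for g in (tf, target):
        if g not in expr.index:
            raise KeyError(f"gene {g} not measured")
    return expr.loc[[tf, target]].mean(axis=0)


def dichotomize(activity: pd.Series) -> pd.Series:
    """High/low labels at the cohort mean; values at the mean go to low."""
    if len(activity) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if activity.nunique() == 1:
        raise ValueError("all activity values identical: one stratum would be empty")
    return pd.Series(
        np.where(activity > activity.mean(), "high", "low"), index=activity.index
    )


def km_logrank(
    labels: pd.Series,
    annot: pd.DataFrame,
    tf: str = "",
    target: str = "",
    tumor: str = "",
    alpha: float = 0.05,
) -> SurvivalResult:
    """Two-stratum Kaplan-Meier comparison with the log-rank test."""
    ann = annot.set_index("sample_id").loc[labels.index]
    durations = ann["survival_days"].to_numpy(dtype=float)
    events = ann["event"].to_numpy(dtype=int)
    if np.isnan(durations).any():
        raise ValueError("missing survival times in the compared samples")
    hi = labels == "high"
    if hi.all() or (~hi).all():
        raise ValueError("both strata must be non-empty")
    if events.sum() == 0:
        raise ValueError("no events observed: log-rank undefined")
    res = logrank_test(durations[hi], durations[~hi], events[hi], events[~hi])
    direction = None
    if res.p_value < alpha:
        tau = float(durations.max())
        rmst = {}
        for name, mask in (("high", hi.to_numpy()), ("low", (~hi).to_numpy())):
            km = KaplanMeierFitter().fit(durations[mask], events[mask])
            rmst[name] = float(restricted_mean_survival_time(km, t=tau))
        direction = "noxious" if rmst["high"] < rmst["low"] else "favorable"
    return SurvivalResult(
        tf=tf,
        target=target,
        tumor=tumor,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
        direction=direction,
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
    )


def survival_scan(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    modules: list[tuple[str, str]],
    tumor: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KM/log-rank over every final module of one tumor cohort.

    Returns one row per module with raw and BH-adjusted P values; the raw
    P at ``alpha`` remains the primary significance call.
    """
    cohort = annot[(annot["tumor_type"] == tumor) & (annot["sample_class"] != "healthy")]
    samples = cohort["sample_id"].tolist()
    rows = []
    for tf, target in sorted(modules):
        activity = module_activity(expr[samples], tf, target)
        labels = dichotomize(activity)
        res = km_logrank(labels, annot, tf=tf, target=target, tumor=tumor, alpha=alpha)
        rows.append(
            {
                "tf": tf,
                "target": target,
                "tumor": tumor,
                "logrank_stat": res.logrank_stat,
                "p": res.logrank_p,
                "direction": res.direction,
                "n_high": res.n_high,
                "n_low": res.n_low,
            }
        )
    table = pd.DataFrame(
        rows, columns=["tf", "target", "tumor", "logrank_stat", "p", "direction", "n_high", "n_low"]
    )
    if not table.empty:
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return table


def direction_consistency(results: pd.DataFrame, alpha: float = 0.05) -> list[dict]:
    """Check that prognostic direction is shared within each TF and target.

    For every TF with >= 2 significant modules (and likewise every
    target), all directions must agree; the returned list of violations
    is empty when the property holds.
    """
    sig = results[(results["p"] < alpha) & results["direction"].notna()]
    violations = []
    for key in ("tf", "target"):
        for name, grp in sig.groupby(key):
            dirs = set(grp["direction"])
            if len(grp) >= 2 and len(dirs) > 1:
                violations.append({"level": key, "gene": name, "directions": sorted(dirs)})
    return violations


def map_druggability(
    architecture: dict[str, set[str]],
    drugs: pd.DataFrame,
    tumor: str,
) -> pd.DataFrame:
    """Partition drug-gene interactions by regulatory layer and label status.

    ``architecture`` maps layer name ("matrisome", "TF", "master") to that
    tumor's gene sets.  FDA-approved cancer drugs are split into on-label
    (approved for this tumor) vs off-label; non-FDA entries keep an empty
    label status.  The drug table must already be mechanism-filtered (see
    :func:`matrisome_atlas.io.load_drug_table`).
    """
    layer_of: dict[str, str] = {}
    for layer in ("master", "TF", "matrisome"):  # masters take precedence
        for gene in architecture.get(layer, set()):
            layer_of.setdefault(gene, layer)
    rows = []
    for row in drugs.itertuples(index=False):
        layer = layer_of.get(row.gene)
        if layer is None:
            warnings.warn(f"drug target {row.gene} outside the {tumor} architecture; skipped")
            continue
        approved = bool(row.fda_approved_cancer_drug)
        label = ""
        if approved:
            approved_types = set(str(row.approved_tumor_types).split(";")) - {""}
            label = "on-label" if tumor in approved_types else "off-label"
        rows.append(
            {
                "layer": layer,
                "drug": row.drug,
                "gene": row.gene,
                "mechanism": row.mechanism,
                "fda_cancer_drug": approved,
                "label_status": label,
            }
        )
    return pd.DataFrame(
        rows, columns=["layer", "drug", "gene", "mechanism", "fda_cancer_drug", "label_status"]
    )
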