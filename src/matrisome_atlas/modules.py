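"""Consensus inference of TF -> matrisome-target regulatory modules.

The pipeline mirrors a multistep consensus scheme:

1. *Mining*: candidate (TF, target) pairs whose target belongs to the
   tumor's signature, supported by at least two prior sources, one of
   which must be functional evidence (CAGE-style TF presence or TF
   binding-site enrichment).
2. *Correlation filter*: Pearson r of each pair inside the tumor of
   interest (r_in) and over the pooled rest of the non-healthy cohort
   (r_rest); negatively or un-correlated pairs (r_in <= 0) are removed
   and both r values are Fisher z-transformed (zCor).
3. *Youden threshold*: the cutpoint maximizing Youden's J between the
   in-tumor and rest-of-cohort zCor samples; a module survives iff
   zCor_in exceeds the threshold and exceeds its own zCor_rest.
4. *Adaptive lasso pruning*: for each target with more than one surviving
   TF, target expression is regressed on the TFs with per-coefficient
   weights 1/|beta_ols| (gamma = 1) and cross-validated penalty; only
   un-shrunk TFs are kept.  The result is "model 1".
5. *Model 2* (sparse Bayesian network): greedy BIC-scored Gaussian
   structure search restricted to the model-1 edge set, repeated over 10
   random 90% subsamples; an edge is kept if selected in >= 50% of folds.
6. *Model 3* (mixed graphical / neighborhood selection): per-target lasso
   over the model-1 TFs, same 10-fold stability rule.
7. *Consensus*: modules present in at least two of the three models;
   because models 2-3 are restricted to model 1, this is
   model1 & (model2 | model3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, LassoLarsIC, Ridge

logger = logging.getLogger(__name__)

FUNCTIONAL_SOURCES = frozenset({"fantom_presence", "tfbs_enrichment"})


@dataclass
class ThresholdResult:
    threshold: float
    j_statistic: float


@dataclass
class PipelineResult:
    """Stage-flagged candidate table plus the per-stage survivor counts."""

    modules: pd.DataFrame
    threshold: ThresholdResult | None
    counts: dict[str, int]

    def final_pairs(self) -> set[tuple[str, str]]:
        final = self.modules[self.modules["final"]]
        return set(zip(final["tf"], final["target"]))


def fisher_z(r):
    """Fisher transformation z = atanh(r) = 0.5*ln((1+r)/(1-r))."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def mine_candidates(priors: pd.DataFrame, signature_genes: set[str], tumor: str) -> pd.DataFrame:
    """Candidate modules: target in signature, >= 2 sources, >= 1 functional."""
    if not signature_genes:
        warnings.warn(f"empty signature for {tumor}: no candidate modules")
        return pd.DataFrame(columns=["tf", "target", "tumor", "sources"])
    hits = priors[priors["target"].isin(signature_genes)]
    rows = []
    for (tf, target), grp in hits.groupby(["tf", "target"], sort=True):
        sources = sorted(set(grp["source"]))
        if len(sources) >= 2 and any(s in FUNCTIONAL_SOURCES for s in sources):
            rows.append(
                {"tf": tf, "target": target, "tumor": tumor, "sources": ";".join(sources)}
            )
    return pd.DataFrame(rows, columns=["tf", "target", "tumor", "sources"])


def correlation_filter(
    candidates: pd.DataFrame,
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    tumor: str,
) -> pd.DataFrame:
    """Attach r_in/r_rest and zCor fields; drop pairs with r_in <= 0.

    r_in uses the tumor's own non-healthy samples; r_rest pools the
    non-healthy samples of every *other* tumor (the owning tumor's samples
    are excluded entirely).
    """
    non_healthy = annot[annot["sample_class"] != "healthy"]
    in_samples = non_healthy.loc[non_healthy["tumor_type"] == tumor, "sample_id"].tolist()
    rest_samples = non_healthy.loc[non_healthy["tumor_type"] != tumor, "sample_id"].tolist()
    out = candidates.copy()
    r_in = np.full(len(out), np.nan)
    r_rest = np.full(len(out), np.nan)
    keep = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.tf not in expr.index or row.target not in expr.index:
            logger.info("candidate (%s, %s) not measured; removed", row.tf, row.target)
            continue
        x_in = expr.loc[row.tf, in_samples].to_numpy()
        y_in = expr.loc[row.target, in_samples].to_numpy()
        x_r = expr.loc[row.tf, rest_samples].to_numpy()
        y_r = expr.loc[row.target, rest_samples].to_numpy()
        if x_in.std() == 0 or y_in.std() == 0 or x_r.std() == 0 or y_r.std() == 0:
            logger.info("constant expression for (%s, %s); removed", row.tf, row.target)
            continue
        r_in[i] = np.corrcoef(x_in, y_in)[0, 1]
        r_rest[i] = np.corrcoef(x_r, y_r)[0, 1]
        keep[i] = r_in[i] > 0
    out["r_in"] = r_in
    out["r_rest"] = r_rest
    out = out[keep].reset_index(drop=True)
    out["zcor_in"] = fisher_z(np.clip(out["r_in"].to_numpy(), -0.999999, 0.999999))
    out["zcor_rest"] = fisher_z(np.clip(out["r_rest"].to_numpy(), -0.999999, 0.999999))
    return out


def youden_threshold(zcor_in_values, zcor_rest_values) -> ThresholdResult:
    """Cutpoint maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutpoints are the midpoints between consecutive distinct
    pooled values; sensitivity is the fraction of in-tumor z values above
    the cutpoint, specificity the fraction of rest-of-cohort z values at
    or below it.  Ties resolve to the smallest maximizing cutpoint.
    """
    z_in = np.asarray(zcor_in_values, dtype=float)
    z_rest = np.asarray(zcor_rest_values, dtype=float)
    if z_in.size == 0 or z_rest.size == 0:
        raise ValueError("both zCor value sets must be non-empty")
    pooled = np.unique(np.concatenate([z_in, z_rest]))
    if pooled.size < 2:
        raise ValueError("all zCor values identical: no separating cutpoint")
    cuts = (pooled[:-1] + pooled[1:]) / 2.0
    sens = (z_in[:, None] > cuts[None, :]).mean(axis=0)
    spec = (z_rest[:, None] <= cuts[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    # smallest maximizing cutpoint; the tolerance absorbs float noise in
    # ties (distinct true J values differ by at least 1/(n_in * n_rest))
    best = int(np.argmax(j >= j.max() - 1e-9))
    return ThresholdResult(threshold=float(cuts[best]), j_statistic=float(j[best]))


def _dedupe_identical_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep one representative per group of bit-identical columns
    (lexicographically first name; names arrive sorted)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        if not any(np.array_equal(X[:, j], X[:, k]) for k in keep):
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def adaptive_lasso_prune(
    expr_tumor: pd.DataFrame,
    target: str,
    tfs: list[str],
    gamma: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Adaptive-lasso variable selection of a target's TFs.

    Initial coefficients come from least squares (ridge when the design is
    rank-deficient); adaptive weights are 1/|beta|**gamma, folded into the
    design so a plain cross-validated lasso selects the penalty.  TFs with
    a nonzero coefficient at the chosen penalty are retained.  A single TF
    is returned unchanged (pruning only applies to multi-TF targets).
    """
    if len(tfs) == 1:
        return list(tfs)
    names = sorted(tfs)
    y = expr_tumor.loc[target].to_numpy(dtype=float)
    if y.size < 2:
        raise ValueError("need >= 2 samples for regression")
    X = expr_tumor.loc[names].to_numpy(dtype=float).T
    X, names = _dedupe_identical_columns(X, names)

    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    ys = y - y.mean()

    rank = np.linalg.matrix_rank(Xs)
    if rank < Xs.shape[1] or Xs.shape[0] <= Xs.shape[1]:
        beta0 = Ridge(alpha=1e-2, fit_intercept=False).fit(Xs, ys).coef_
    else:
        beta0, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    w = np.abs(beta0) ** gamma
    w = np.maximum(w, 1e-8)

    Xw = Xs * w  # lasso coef b_j maps back to beta_j = w_j * b_j
    cv = min(5, max(2, Xs.shape[0] // 10))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(cv=cv, alphas=50, random_state=seed, max_iter=5000).fit(Xw, ys)
    return [n for n, c in zip(names, model.coef_) if abs(c) > 1e-10]


def _subsample_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    size = max(int(round(0.9 * n)), 2)
    return [rng.choice(n, size=size, replace=False) for _ in range(folds)]


def _bic_greedy_parents(y: np.ndarray, X: np.ndarray) -> list[int]:
    """Greedy forward selection of Gaussian-linear parents by BIC."""
    n = y.size
    chosen: list[int] = []
    resid = y - y.mean()
    best_bic = n * np.log(max(np.mean(resid**2), 1e-300)) + np.log(n)  # intercept only
    remaining = list(range(X.shape[1]))
    while remaining:
        trial_bics = []
        for j in remaining:
            cols = chosen + [j]
            A = np.column_stack([np.ones(n), X[:, cols]])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = np.mean((y - A @ coef) ** 2)
            k = len(cols) + 1
            trial_bics.append(n * np.log(max(rss, 1e-300)) + k * np.log(n))
        i_best = int(np.argmin(trial_bics))
        if trial_bics[i_best] < best_bic - 1e-9:
            best_bic = trial_bics[i_best]
            chosen.append(remaining.pop(i_best))
        else:
            break
    return chosen


def model2_sparse_bayes(
    expr_tumor: pd.DataFrame,
    model1_modules: set[tuple[str, str]],
    folds: int = 10,
    stability: float = 0.5,
    seed: int = 0,
) -> set[tuple[str, str]]:
    """Sparse Bayesian-network confirmation of the model-1 edges.

    A score-based structure search (greedy forward selection under the
    Gaussian BIC, a sparsity-inducing score) is run per target with
    candidate parents restricted to its model-1 TFs, on ``folds`` random
    90% subsamples.  An edge is reported iff selected in >= ``stability``
    of the folds.
    """
    if not model1_modules:
        return set()
    n = expr_tumor.shape[1]
    if n < 20:
        raise ValueError("structure search unreliable below 20 samples")
    rng = np.random.default_rng(seed)
    by_target: dict[str, list[str]] = {}
    for tf, target in sorted(model1_modules):
        by_target.setdefault(target, []).append(tf)
    folds_idx = _subsample_folds(n, folds, rng)
    votes: dict[tuple[str, str], int] = {e: 0 for e in model1_modules}
    for idx in folds_idx:
        for target, tfs in by_target.items():
            y = expr_tumor.loc[target].to_numpy(dtype=float)[idx]
            X = expr_tumor.loc[tfs].to_numpy(dtype=float).T[idx]
            for j in _bic_greedy_parents(y, X):
                votes[(tfs[j], target)] += 1
    return {e for e, v in votes.items() if v / folds >= stability}


def model3_mixed_graphical(
    expr_tumor: pd.DataFrame,
    model1_modules: set[tuple[str, str]],
    folds: int = 10,
    stability: float = 0.5,
    seed: int = 0,
) -> set[tuple[str, str]]:
    """Neighborhood-selection confirmation of the model-1 edges.

    Per target, an L1-penalized regression on its model-1 TFs (penalty
    chosen by BIC on the standardized design) estimates conditional
    dependence; the same 90%-subsample stability rule as model 2 applies.
    """
    if not model1_modules:
        return set()
    n = expr_tumor.shape[1]
    if n < 20:
        raise ValueError("structure search unreliable below 20 samples")
    rng = np.random.default_rng(seed)
    by_target: dict[str, list[str]] = {}
    for tf, target in sorted(model1_modules):
        by_target.setdefault(target, []).append(tf)
    folds_idx = _subsample_folds(n, folds, rng)
    votes: dict[tuple[str, str], int] = {e: 0 for e in model1_modules}
    for idx in folds_idx:
        for target, tfs in by_target.items():
            y = expr_tumor.loc[target].to_numpy(dtype=float)[idx]
            X = expr_tumor.loc[tfs].to_numpy(dtype=float).T[idx]
            sd = X.std(axis=0)
            Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
            ys = y - y.mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = LassoLarsIC(criterion="bic").fit(Xs, ys)
            for j, c in enumerate(model.coef_):
                if abs(c) > 1e-10:
                    votes[(tfs[j], target)] += 1
    return {e for e, v in votes.items() if v / folds >= stability}


def consensus(
    model1: set[tuple[str, str]],
    model2: set[tuple[str, str]],
    model3: set[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Modules present in >= 2 of the three models.

    Because models 2 and 3 are restricted to the model-1 edge set, this
    reduces to model1 & (model2 | model3); edges outside model 1 can never
    reach two memberships and are dropped.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in (model1, model2, model3):
        for e in s:
            counts[e] = counts.get(e, 0) + 1
    return {e for e, c in counts.items() if c >= 2 and e in model1}


def staining_crossval(proteins: list[str], staining: pd.DataFrame) -> pd.DataFrame:
    """Percentile Positive Staining per protein.

    PPS = 100 * (#High + #Medium) / #assayed samples; a protein is
    cross-validated iff PPS > 0.  Proteins absent from the staining table
    are reported as not assayed (PPS = NaN) and excluded from the
    validation denominator.
    """
    rows = []
    grouped = staining.groupby("protein")
    for p in sorted(set(proteins)):
        if p in grouped.groups:
            levels = grouped.get_group(p)["level"]
            pps = 100.0 * levels.isin(["High", "Medium"]).mean()
            rows.append({"protein": p, "assayed": True, "pps": pps, "validated": pps > 0})
        else:
            rows.append({"protein": p, "assayed": False, "pps": np.nan, "validated": False})
    return pd.DataFrame(rows, columns=["protein", "assayed", "pps", "validated"])


def run_module_pipeline(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    priors: pd.DataFrame,
    signature_genes: set[str],
    tumor: str,
    folds: int = 10,
    stability: float = 0.5,
    seed: int = 0,
) -> PipelineResult:
    """Run the full consensus pipeline for one tumor.

    Returns the stage-flagged module table (columns tf, target, tumor,
    sources, r_in, r_rest, zcor_in, zcor_rest, passed_youden,
    in_model1..3, final) and the per-stage counts, which shrink
    monotonically by construction.
    """
    counts: dict[str, int] = {}
    mined = mine_candidates(priors, signature_genes, tumor)
    counts["mined"] = len(mined)
    if mined.empty:
        empty = mined.assign(
            r_in=[], r_rest=[], zcor_in=[], zcor_rest=[], passed_youden=[],
            in_model1=[], in_model2=[], in_model3=[], final=[],
        )
        counts.update(post_correlation=0, post_youden=0, model1=0, final=0)
        return PipelineResult(modules=empty, threshold=None, counts=counts)

    table = correlation_filter(mined, expr, annot, tumor)
    counts["post_correlation"] = len(table)
    if table.empty:
        table = table.assign(passed_youden=[], in_model1=[], in_model2=[], in_model3=[], final=[])
        counts.update(post_youden=0, model1=0, final=0)
        return PipelineResult(modules=table, threshold=None, counts=counts)

    thr = youden_threshold(table["zcor_in"].to_numpy(), table["zcor_rest"].to_numpy())
    table["passed_youden"] = (table["zcor_in"] > thr.threshold) & (
        table["zcor_in"] > table["zcor_rest"]
    )
    counts["post_youden"] = int(table["passed_youden"].sum())

    non_healthy = annot[annot["sample_class"] != "healthy"]
    in_samples = non_healthy.loc[non_healthy["tumor_type"] == tumor, "sample_id"].tolist()
    expr_tumor = expr[in_samples]

    surviving = table[table["passed_youden"]]
    model1: set[tuple[str, str]] = set()
    for target, grp in surviving.groupby("target"):
        tfs = sorted(grp["tf"])
        kept = adaptive_lasso_prune(expr_tumor, target, tfs, seed=seed) if len(tfs) > 1 else tfs
        model1 |= {(tf, target) for tf in kept}
    table["in_model1"] = [
        (tf, tg) in model1 for tf, tg in zip(table["tf"], table["target"])
    ]
    counts["model1"] = len(model1)

    m2 = model2_sparse_bayes(expr_tumor, model1, folds=folds, stability=stability, seed=seed)
    m3 = model3_mixed_graphical(expr_tumor, model1, folds=folds, stability=stability, seed=seed)
    final = consensus(model1, m2, m3)
    table["in_model2"] = [(tf, tg) in m2 for tf, tg in zip(table["tf"], table["target"])]
    table["in_model3"] = [(tf, tg) in m3 for tf, tg in zip(table["tf"], table["target"])]
    table["final"] = [(tf, tg) in final for tf, tg in zip(table["tf"], table["target"])]
    counts["final"] = len(final)
    return PipelineResult(modules=table, threshold=thr, counts=counts)
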