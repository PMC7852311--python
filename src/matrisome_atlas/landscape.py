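"""Global expression landscape: per-tumor gene ranking, inter-tumor
correlation clustering, and multi-classifier recall with contingency tests.

The classification protocol mirrors a three-algorithm consensus: an RBF
support-vector machine, a small feed-forward neural network, and a
decision tree, each evaluated over repeated random 80/20 train/test splits
with standardization fit on the training fold only.  Per-tumor recall is
averaged within each algorithm and then (unweighted) across algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


@dataclass
class RecallTable:
    recall_per_algorithm: pd.DataFrame  # tumors x algorithms
    mean_recall: pd.Series  # per tumor
    confusion_counts: pd.DataFrame  # true x predicted, pooled over all runs


@dataclass
class CorrelationClusterResult:
    correlation: pd.DataFrame
    clusters: dict[str, int]
    k_genes: int


def _tumor_samples(annot: pd.DataFrame) -> pd.DataFrame:
    return annot[annot["sample_class"] != "healthy"]


def rank_genes_per_tumor(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    k: int,
    direction: str = "most",
) -> dict[str, list[str]]:
    """Top-k genes by mean expression per tumor (non-healthy samples only).

    ``direction="most"`` returns the k highest-mean genes in descending
    order; ``"least"`` the k lowest in ascending order.  Ties break
    lexicographically by gene identifier.
    """
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {expr.shape[0]}")
    if direction not in ("most", "least"):
        raise ValueError("direction must be 'most' or 'least'")
    tumor_annot = _tumor_samples(annot)
    out: dict[str, list[str]] = {}
    for tumor, grp in tumor_annot.groupby("tumor_type", sort=True):
        means = expr[grp["sample_id"]].mean(axis=1)
        frame = pd.DataFrame({"mean": means, "gene": means.index})
        ascending = direction == "least"
        ranked = frame.sort_values(["mean", "gene"], ascending=[ascending, True])
        out[str(tumor)] = ranked["gene"].head(k).tolist()
    return out


def inter_tumor_correlation(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    k: int = 100,
    cut_height: float = 0.5,
    direction: str = "most",
) -> CorrelationClusterResult:
    """Pairwise Pearson correlation of tumor mean-expression profiles.

    The gene universe is the union of per-tumor top-k lists; each tumor is
    summarized by its mean-expression vector over that universe, and
    tumors are clustered by average linkage on distance 1 - r cut at
    ``cut_height``.
    """
    top = rank_genes_per_tumor(expr, annot, k, direction)
    tumors = sorted(top)
    if len(tumors) < 2:
        raise ValueError("need >= 2 tumor types")
    universe = sorted(set().union(*top.values()))
    tumor_annot = _tumor_samples(annot)
    profiles = {}
    for tumor in tumors:
        samples = tumor_annot.loc[tumor_annot["tumor_type"] == tumor, "sample_id"]
        vec = expr.loc[universe, samples].mean(axis=1).to_numpy()
        if np.std(vec) == 0:
            raise ValueError(f"constant mean-expression vector for tumor {tumor}")
        profiles[tumor] = vec
    mat = np.corrcoef(np.array([profiles[t] for t in tumors]))
    np.fill_diagonal(mat, 1.0)
    corr = pd.DataFrame(mat, index=tumors, columns=tumors)
    dist = squareform(np.clip(1.0 - mat, 0.0, None), checks=False)
    labels = fcluster(linkage(dist, method="average"), t=cut_height, criterion="distance")
    clusters = {t: int(c) for t, c in zip(tumors, labels)}
    return CorrelationClusterResult(correlation=corr, clusters=clusters, k_genes=k)


def _default_algorithms(seed: int):
    return {
        "svm": make_pipeline(
            StandardScaler(), SVC(kernel="rbf", gamma="scale", random_state=seed)
        ),
        "nn": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=250, random_state=seed),
        ),
        "tree": make_pipeline(StandardScaler(), DecisionTreeClassifier(random_state=seed)),
    }


def classify_tumors(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    scheme: tuple[str, ...] = ("svm", "nn", "tree"),
    cv_spec: dict[str, int] | None = None,
    seed: int = 0,
) -> RecallTable:
    """Per-tumor recall from a multi-classifier consensus with repeated CV.

    ``cv_spec`` maps algorithm name to the number of random 80/20 splits
    (defaults: 100 for the margin classifier, 10 for the others).
    """
    cv_spec = dict(cv_spec or {"svm": 100, "nn": 10, "tree": 10})
    tumor_annot = _tumor_samples(annot)
    counts = tumor_annot["tumor_type"].value_counts()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"every tumor needs >= 5 samples; too few in {small}")
    tumors = sorted(counts.index)
    X = expr[tumor_annot["sample_id"]].to_numpy().T
    y = tumor_annot["tumor_type"].to_numpy()

    algorithms = {name: est for name, est in _default_algorithms(seed).items() if name in scheme}
    if not algorithms:
        raise ValueError(f"no known algorithm in scheme {scheme!r}")
    recall = pd.DataFrame(index=tumors, columns=list(algorithms), dtype=float)
    confusion = pd.DataFrame(0, index=tumors, columns=tumors, dtype=int)

    for name, est in algorithms.items():
        n_splits = cv_spec.get(name, 10)
        splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=0.2, random_state=seed)
        per_run = np.full((n_splits, len(tumors)), np.nan)
        for run, (tr, te) in enumerate(splitter.split(X, y)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # NN convergence at capped steps
                est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            truth = y[te]
            for ti, tumor in enumerate(tumors):
                mask = truth == tumor
                if mask.any():
                    per_run[run, ti] = np.mean(pred[mask] == tumor)
            for yt, yp in zip(truth, pred):
                confusion.loc[yt, yp] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            recall[name] = np.nanmean(per_run, axis=0)
        missing = recall[name].isna()
        if missing.any():
            warnings.warn(
                f"tumor(s) {recall.index[missing].tolist()} absent from every "
                f"test split of {name}; recall reported as missing"
            )
    return RecallTable(
        recall_per_algorithm=recall,
        mean_recall=recall.mean(axis=1, skipna=True),
        confusion_counts=confusion,
    )


def contingency_test(table) -> tuple[float, float]:
    """Chi-square test on a 2-D count table.

    Yates continuity correction is applied on 2x2 tables; larger tables use
    the plain Pearson statistic.  Returns (statistic, p_value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if min(arr.shape) < 2:
        raise ValueError("zero-margin or degenerate table: need >= 2 rows and >= 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column in contingency table")
    correction = arr.shape == (2, 2)
    stat, p, _, _ = chi2_contingency(arr, correction=correction)
    return float(stat), float(p)
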