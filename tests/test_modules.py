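"""Consensus-engine contracts: mining rule, Fisher z, Youden cutpoint vs a
brute-force oracle, adaptive-lasso support recovery, model 2/3 stability,
consensus rule, staining cross-validation, and monotone shrinkage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matrisome_atlas import (
    adaptive_lasso_prune,
    consensus,
    correlation_filter,
    fisher_z,
    mine_candidates,
    model2_sparse_bayes,
    model3_mixed_graphical,
    run_module_pipeline,
    staining_crossval,
    youden_threshold,
)


# ---------------------------------------------------------------- fisher_z
class TestFisherZ:
    def test_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3), rel=1e-12)
        assert round(fisher_z(0.5), 4) == 0.5493

    def test_antisymmetry_and_closed_form_grid(self):
        grid = np.linspace(-0.99, 0.99, 199)
        z = fisher_z(grid)
        assert np.allclose(z, -fisher_z(-grid), rtol=1e-12)
        expected = 0.5 * np.log((1 + grid) / (1 - grid))
        assert np.allclose(z, expected, rtol=1e-12)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError, match="fisher_z"):
            fisher_z(r)


# ------------------------------------------------------------------ mining
def _priors(rows):
    return pd.DataFrame(rows, columns=["tf", "target", "source"])


class TestMining:
    def test_textual_plus_functional_retained(self):
        priors = _priors([("TF1", "m1", "sourceA"), ("TF1", "m1", "fantom_presence")])
        out = mine_candidates(priors, {"m1"}, "T")
        assert list(zip(out["tf"], out["target"])) == [("TF1", "m1")]

    def test_two_textual_sources_dropped(self):
        priors = _priors([("TF1", "m1", "sourceA"), ("TF1", "m1", "sourceB")])
        assert mine_candidates(priors, {"m1"}, "T").empty

    def test_single_functional_source_dropped(self):
        priors = _priors([("TF1", "m1", "fantom_presence")])
        assert mine_candidates(priors, {"m1"}, "T").empty

    def test_target_outside_signature_dropped(self):
        priors = _priors([("TF1", "m1", "sourceA"), ("TF1", "m1", "tfbs_enrichment")])
        assert mine_candidates(priors, {"other"}, "T").empty

    def test_empty_signature_warns(self):
        with pytest.warns(UserWarning, match="empty signature"):
            out = mine_candidates(_priors([("TF1", "m1", "sourceA")]), set(), "T")
        assert out.empty


# ------------------------------------------------------------------ youden
def youden_bruteforce(z_in, z_rest):
    """Independent oracle: exhaustive scan over midpoint cutpoints."""
    pooled = sorted(set(list(z_in) + list(z_rest)))
    best = (None, -np.inf)
    for lo, hi in zip(pooled, pooled[1:]):
        c = (lo + hi) / 2.0
        sens = sum(z > c for z in z_in) / len(z_in)
        spec = sum(z <= c for z in z_rest) / len(z_rest)
        j = sens + spec - 1.0
        if j > best[1] + 1e-9:
            best = (c, j)
    return best


class TestYouden:
    def test_separated_sets(self):
        res = youden_threshold([2, 3, 4], [0, 0.5, 1])
        assert res.threshold == pytest.approx(1.5)
        assert res.j_statistic == pytest.approx(1.0)

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="no separating cutpoint"):
            youden_threshold([1.0, 1.0], [1.0])

    def test_large_shift_reaches_perfect_separation(self):
        rng = np.random.default_rng(0)
        rest = rng.normal(0, 1, 50)
        res = youden_threshold(rest + 100.0, rest)
        assert res.j_statistic == pytest.approx(1.0)

    def test_no_separation_gives_small_j(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 500)
        res = youden_threshold(vals, rng.permutation(vals))
        assert res.j_statistic < 0.2

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(-50, 50), min_size=1, max_size=50),
        st.lists(st.integers(-50, 50), min_size=1, max_size=50),
    )
    def test_agrees_with_bruteforce(self, a, b):
        z_in = [x / 10 for x in a]
        z_rest = [x / 10 for x in b]
        if len(set(z_in) | set(z_rest)) < 2:
            return
        res = youden_threshold(z_in, z_rest)
        c, j = youden_bruteforce(z_in, z_rest)
        assert res.j_statistic == pytest.approx(j, abs=1e-12)
        assert res.threshold == pytest.approx(c, abs=1e-12)


# ------------------------------------------------------- correlation filter
def _pair_cohort(r_in, r_rest, n=150, seed=0):
    rng = np.random.default_rng(seed)
    samples, rows, cols = [], [], []
    for tumor, r in (("A", r_in), ("B", r_rest)):
        x = rng.normal(0, 1, n)
        y = r * x + np.sqrt(1 - r * r) * rng.normal(0, 1, n)
        for i in range(n):
            s = f"{tumor}{i}"
            samples.append(s)
            rows.append({"sample_id": s, "tumor_type": tumor, "sample_class": "primary"})
            cols.append((8 + x[i], 8 + y[i]))
    expr = pd.DataFrame(np.array(cols).T, index=["TF1", "m1"], columns=samples)
    return expr, pd.DataFrame(rows)


class TestCorrelationFilter:
    def _cands(self):
        return pd.DataFrame(
            [{"tf": "TF1", "target": "m1", "tumor": "A", "sources": "sourceA;fantom_presence"}]
        )

    def test_planted_pair_retains_expected_zcor(self):
        expr, annot = _pair_cohort(0.8, 0.1)
        out = correlation_filter(self._cands(), expr, annot, "A")
        assert len(out) == 1
        assert out["zcor_in"].iloc[0] == pytest.approx(np.arctanh(0.8), abs=0.25)

    def test_anticorrelated_pair_removed(self):
        expr, annot = _pair_cohort(-0.8, 0.1)
        assert correlation_filter(self._cands(), expr, annot, "A").empty

    def test_rest_excludes_owning_tumor(self):
        # pair perfectly correlated in A, anti-correlated in B: if A leaked
        # into the rest pool, r_rest would be pulled far above -0.9
        expr, annot = _pair_cohort(0.95, -0.95)
        out = correlation_filter(self._cands(), expr, annot, "A")
        assert out["r_rest"].iloc[0] < -0.85

    def test_constant_vector_removed(self):
        expr, annot = _pair_cohort(0.8, 0.1)
        expr.loc["m1", [c for c in expr.columns if c.startswith("A")]] = 5.0
        assert correlation_filter(self._cands(), expr, annot, "A").empty


# ------------------------------------------------------------ adaptive lasso
def _tumor_expr(columns: dict[str, np.ndarray]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"s{i}" for i in range(n)]).T


class TestAdaptiveLasso:
    def test_true_support_recovered(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tf1 = rng.normal(0, 1, 300)
            tf2 = rng.normal(0, 1, 300)
            y = 2.0 * tf1 + rng.normal(0, 1, 300)
            expr = _tumor_expr({"TF1": tf1, "TF2": tf2, "m1": y})
            if adaptive_lasso_prune(expr, "m1", ["TF1", "TF2"], seed=0) == ["TF1"]:
                wins += 1
        assert wins >= 5 * 0.95 - 1  # >= 95% of replicates

    def test_single_tf_is_identity(self):
        expr = _tumor_expr({"TF9": np.arange(10.0), "m1": np.arange(10.0)})
        assert adaptive_lasso_prune(expr, "m1", ["TF9"]) == ["TF9"]

    def test_duplicated_tfs_tie_break_lexicographic(self):
        rng = np.random.default_rng(0)
        tf = rng.normal(0, 1, 200)
        y = tf + rng.normal(0, 0.5, 200)
        expr = _tumor_expr({"TFB": tf, "TFA": tf.copy(), "m1": y})
        assert adaptive_lasso_prune(expr, "m1", ["TFB", "TFA"], seed=0) == ["TFA"]

    def test_too_few_samples_errors(self):
        expr = _tumor_expr({"TF1": np.array([1.0]), "TF2": np.array([2.0]), "m1": np.array([1.0])})
        with pytest.raises(ValueError, match="samples"):
            adaptive_lasso_prune(expr, "m1", ["TF1", "TF2"])


# ---------------------------------------------------------------- models 2/3
def _model_cohort(seed=0, n=200):
    rng = np.random.default_rng(seed)
    tf1 = rng.normal(0, 1, n)
    tf2 = rng.normal(0, 1, n)
    strong = 0.8 * tf1 + 0.6 * rng.normal(0, 1, n)
    null = rng.normal(0, 1, n)
    return _tumor_expr({"TF1": tf1, "TF2": tf2, "mS": strong, "mN": null})


@pytest.mark.parametrize("model", [model2_sparse_bayes, model3_mixed_graphical])
class TestConfirmationModels:
    def test_strong_edge_kept_null_edge_rejected(self, model):
        expr = _model_cohort()
        model1 = {("TF1", "mS"), ("TF2", "mN")}
        out = model(expr, model1, seed=0)
        assert ("TF1", "mS") in out
        assert ("TF2", "mN") not in out

    def test_output_subset_of_model1(self, model):
        expr = _model_cohort(seed=1)
        model1 = {("TF1", "mS"), ("TF2", "mS"), ("TF1", "mN")}
        assert model(expr, model1, seed=0) <= model1

    def test_empty_model1_gives_empty_output(self, model):
        assert model(_model_cohort(), set(), seed=0) == set()

    def test_too_few_samples_error(self, model):
        expr = _model_cohort(n=10)
        with pytest.raises(ValueError, match="20 samples"):
            model(expr, {("TF1", "mS")}, seed=0)


def test_model3_conditional_pruning_of_redundant_tf():
    rng = np.random.default_rng(3)
    tf1 = rng.normal(0, 1, 300)
    tf2 = tf1 + rng.normal(0, 0.1, 300)  # near-copy of TF1
    y = tf1 + rng.normal(0, 1, 300)
    expr = _tumor_expr({"TF1": tf1, "TF2": tf2, "m1": y})
    out = model3_mixed_graphical(expr, {("TF1", "m1"), ("TF2", "m1")}, seed=0)
    # given TF1, TF2 carries no extra signal: it must not outlive TF1
    assert ("TF1", "m1") in out or out == set()
    assert not (("TF2", "m1") in out and ("TF1", "m1") not in out)


# --------------------------------------------------------------- consensus
class TestConsensus:
    def test_two_model_membership_kept(self):
        assert consensus({("a", "b")}, {("a", "b")}, set()) == {("a", "b")}

    def test_model3_only_is_dropped(self):
        assert consensus(set(), set(), {("a", "b")}) == set()

    def test_all_three_kept(self):
        e = {("a", "b")}
        assert consensus(e, e, e) == e


# ---------------------------------------------------------------- staining
class TestStainingCrossval:
    def test_pps_two_of_three(self):
        staining = pd.DataFrame(
            {
                "protein": ["P1"] * 3,
                "sample_id": ["s1", "s2", "s3"],
                "level": ["High", "Medium", "Low"],
            }
        )
        out = staining_crossval(["P1"], staining)
        assert round(out["pps"].iloc[0], 1) == 66.7
        assert bool(out["validated"].iloc[0])

    def test_all_not_detected_is_not_validated(self):
        staining = pd.DataFrame(
            {"protein": ["P1"] * 2, "sample_id": ["s1", "s2"], "level": ["Not detected"] * 2}
        )
        out = staining_crossval(["P1"], staining)
        assert out["pps"].iloc[0] == 0.0
        assert not bool(out["validated"].iloc[0])

    def test_absent_protein_is_not_assayed(self):
        staining = pd.DataFrame(
            {"protein": ["P1"], "sample_id": ["s1"], "level": ["High"]}
        )
        out = staining_crossval(["P1", "P2"], staining).set_index("protein")
        assert not bool(out.loc["P2", "assayed"])
        assert np.isnan(out.loc["P2", "pps"])


# ----------------------------------------------------------- full pipeline
def test_pipeline_counts_shrink_monotonically(small_data, small_signatures):
    truth = small_data["truth"]
    for tumor in truth.tumor_types:
        res = run_module_pipeline(
            small_data["expr"],
            small_data["annot"],
            small_data["priors"],
            small_signatures[tumor].genes,
            tumor,
            seed=0,
        )
        c = res.counts
        assert c["final"] <= c["model1"] <= c["post_youden"] <= c["post_correlation"] <= c["mined"]


def test_final_modules_satisfy_zcor_dominance(small_data, small_signatures):
    res = run_module_pipeline(
        small_data["expr"],
        small_data["annot"],
        small_data["priors"],
        small_signatures["TUM01"].genes,
        "TUM01",
        seed=0,
    )
    final = res.modules[res.modules["final"]]
    assert not final.empty
    assert (final["r_in"] > 0).all()
    assert (final["zcor_in"] > res.threshold.threshold).all()
    assert (final["zcor_in"] > final["zcor_rest"]).all()
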