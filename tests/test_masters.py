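"""Driver filters at their exact boundaries, PPI linkage, summaries,
cluster-level regulator extraction, and pathway over-representation."""

import math

import numpy as np
import pandas as pd
import pytest

from matrisome_atlas import (
    MasterRegulator,
    cluster_regulator_selection,
    filter_drivers,
    find_masters,
    link_masters,
    pathway_enrichment,
    regulator_summary,
)


def _drivers(rows):
    return pd.DataFrame(rows, columns=["gene", "tumor_type", "mutation_frequency", "driver_class"])


class TestFrequencyFilter:
    def test_specific_strictly_above_five_percent(self):
        drv = _drivers(
            [
                ("gKEEP", "T", 0.06, "tumor-specific"),
                ("gEDGE", "T", 0.05, "tumor-specific"),
                ("gLOW", "T", 0.04, "tumor-specific"),
            ]
        )
        assert list(filter_drivers(drv, "T")["gene"]) == ["gKEEP"]

    def test_pan_cancer_above_own_mean(self):
        drv = _drivers(
            [
                ("gPAN", "T", 0.10, "pan-cancer"),
                ("gPAN", "U", 0.08, "pan-cancer"),
                ("gPAN", "V", 0.06, "pan-cancer"),  # mean = 0.08 < 0.10 in T
                ("gFLAT", "T", 0.07, "pan-cancer"),
                ("gFLAT", "U", 0.07, "pan-cancer"),  # at its own mean in T -> dropped
            ]
        )
        assert list(filter_drivers(drv, "T")["gene"]) == ["gPAN"]

    def test_missing_frequency_warns_and_skips(self):
        drv = _drivers([("gNA", "T", np.nan, "tumor-specific")])
        with pytest.warns(UserWarning, match="gNA"):
            assert filter_drivers(drv, "T").empty


class TestPPILinkage:
    def _candidates(self, genes):
        return pd.DataFrame(
            [{"gene": g, "driver_class": "tumor-specific", "frequency": 0.2} for g in genes]
        )

    def _ppi(self, edges):
        return pd.DataFrame(edges, columns=["protein_a", "protein_b"]).assign(evidence="test")

    def test_coverage_strictly_above_ten_percent(self):
        tfs = {f"TF{i:02d}" for i in range(20)}
        ppi = self._ppi(
            [("gMASTER", f"TF{i:02d}") for i in range(3)]  # 3/20 = 15%
            + [("gEDGE", f"TF{i:02d}") for i in range(2)]  # 2/20 = 10% exactly
        )
        masters = link_masters(self._candidates(["gMASTER", "gEDGE"]), ppi, tfs, "T")
        assert [m.driver for m in masters] == ["gMASTER"]
        assert masters[0].coverage == pytest.approx(0.15)

    def test_empty_ppi_warns_and_returns_nothing(self):
        with pytest.warns(UserWarning, match="empty PPI"):
            out = link_masters(self._candidates(["g1"]), self._ppi([]).iloc[0:0], {"TF1"}, "T")
        assert out == []

    def test_generator_masters_exactly_recovered(self, small_data):
        truth = small_data["truth"]
        for tumor in truth.tumor_types:
            found = {
                m.driver
                for m in find_masters(
                    small_data["drivers"], small_data["ppi"], truth.module_tfs(tumor), tumor
                )
            }
            assert found == truth.planted_masters[tumor]


class TestSummary:
    def _master(self, gene, tumor, n_partners, cls="tumor-specific"):
        return MasterRegulator(
            driver=gene,
            tumor=tumor,
            driver_class=cls,
            tf_partners={f"TF{i}" for i in range(n_partners)},
            coverage=0.5,
        )

    def test_weighted_average_tfs_per_master(self):
        summary = regulator_summary(
            {"T": [self._master("g1", "T", 3), self._master("g2", "T", 5)]}
        )
        assert summary["weighted_avg_tfs_per_master"] == pytest.approx(4.0)

    def test_common_vs_unique_partition(self):
        summary = regulator_summary(
            {
                "T": [self._master("gC", "T", 2), self._master("gU", "T", 2)],
                "U": [self._master("gC", "U", 2)],
            }
        )
        assert summary["common_regulators"] == ["gC"]
        assert summary["unique_regulators"] == ["gU"]

    def test_empty_input_is_empty_summary(self):
        summary = regulator_summary({})
        assert summary["per_tumor"] == {}
        assert math.isnan(summary["weighted_avg_tfs_per_master"])


def _cluster_cohort(shift, seed=0):
    """Four tumors, 30 samples each; five regulator genes shifted by
    ``shift`` in the two cluster tumors."""
    rng = np.random.default_rng(seed)
    genes = [f"REG{i}" for i in range(5)] + [f"BG{i}" for i in range(5)]
    samples, rows = [], []
    for t in ("A", "B", "C", "D"):
        for j in range(30):
            s = f"{t}{j}"
            samples.append(s)
            rows.append({"sample_id": s, "tumor_type": t, "sample_class": "primary"})
    X = rng.normal(8, 1, (10, len(samples)))
    in_cluster = [i for i, s in enumerate(samples) if s[0] in "AB"]
    X[:5, in_cluster] += shift
    expr = pd.DataFrame(X, index=genes, columns=samples)
    masters = {
        t: [
            MasterRegulator(f"REG{i}", t, "tumor-specific", {"TF1"}, 0.5)
            for i in range(5)
        ]
        for t in ("A", "B")
    }
    return expr, pd.DataFrame(rows), masters


class TestClusterSelection:
    def test_separable_cluster_reaches_high_auc(self):
        expr, annot, masters = _cluster_cohort(shift=3.0)
        out = cluster_regulator_selection(masters, expr, annot, {"A", "B"}, seed=0)
        assert out["regulators"] == [f"REG{i}" for i in range(5)]
        assert out["auc"] > 0.9
        assert sum(out["importances"].values()) == pytest.approx(1.0)

    def test_no_signal_auc_near_chance(self):
        expr, annot, masters = _cluster_cohort(shift=0.0, seed=1)
        out = cluster_regulator_selection(masters, expr, annot, {"A", "B"}, seed=0)
        assert 0.3 < out["auc"] < 0.7

    def test_auc_invariant_to_sample_order(self):
        expr, annot, masters = _cluster_cohort(shift=3.0)
        out1 = cluster_regulator_selection(masters, expr, annot, {"A", "B"}, seed=0)
        perm = annot.sample(frac=1.0, random_state=3).reset_index(drop=True)
        out2 = cluster_regulator_selection(masters, expr, perm, {"A", "B"}, seed=0)
        assert out1["auc"] == pytest.approx(out2["auc"], abs=0.1)

    def test_single_shared_regulator_importance_is_one(self):
        expr, annot, masters = _cluster_cohort(shift=3.0)
        masters = {t: ms[:1] for t, ms in masters.items()}
        out = cluster_regulator_selection(masters, expr, annot, {"A", "B"}, seed=0)
        assert out["importances"] == {"REG0": 1.0}

    def test_empty_intersection_warns(self):
        expr, annot, masters = _cluster_cohort(shift=3.0)
        masters["B"] = []
        with pytest.warns(UserWarning, match="shared"):
            out = cluster_regulator_selection(masters, expr, annot, {"A", "B"}, seed=0)
        assert out["regulators"] == []


class TestPathwayEnrichment:
    def test_entire_pathway_query_matches_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(1000)}
        pathway = {f"g{i}" for i in range(10)}
        other = {f"g{i}" for i in range(500, 520)}
        out = pathway_enrichment(
            pathway, {"hit": pathway, "other": other}, universe
        ).set_index("pathway")
        # oracle: P(overlap = 10 of 10 drawn) = 1 / C(1000, 10)
        expected = 1.0 / math.comb(1000, 10)
        assert out.loc["hit", "p_value"] == pytest.approx(expected, rel=1e-6)
        assert out.loc["hit", "p_value"] == out["p_value"].min()

    def test_disjoint_query_p_is_one(self):
        universe = {f"g{i}" for i in range(100)}
        out = pathway_enrichment({"g1"}, {"pw": {"g50", "g51"}}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_mutational_activation_needs_two_specific_masters(self):
        universe = {f"g{i}" for i in range(100)}
        pw = {"pw": {"g1", "g2", "g3"}}
        two = pathway_enrichment({"g1", "g2"}, pw, universe, specific_masters={"g1", "g2"})
        one = pathway_enrichment({"g1", "g2"}, pw, universe, specific_masters={"g1"})
        assert bool(two["mutationally_activated"].iloc[0])
        assert not bool(one["mutationally_activated"].iloc[0])

    def test_gene_outside_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            pathway_enrichment({"alien"}, {"pw": {"g1"}}, {"g1", "g2"})
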