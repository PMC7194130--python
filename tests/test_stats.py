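"""Richness/cover summaries, ANOVA designs, Tukey, assumption checks."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import summitveg as sv
from summitveg.errors import DegenerateDesignError
from summitveg.stats import (
    assumption_checks,
    cover_change_table,
    factor_effects,
    group_summary,
    richness_per_quadrat,
    total_cover_per_quadrat,
    tukey_posthoc,
)


class TestRichness:
    def test_counts_distinct_species(self, tiny_observations):
        rich = richness_per_quadrat(tiny_observations)
        q1 = rich[(rich["quadrat_index"] == 1) & (rich["year"] == 2014)]
        assert q1["richness"].iloc[0] == 2

    def test_group_summary_aggregates_consistently(self, default_survey):
        observations, _, _ = default_survey
        rich = richness_per_quadrat(observations)
        by_summit = group_summary(rich, "richness", ["summit_id", "year"])
        by_aspect = group_summary(rich, "richness", ["summit_id", "aspect", "year"])
        for _, row in by_summit.iterrows():
            sub = by_aspect[(by_aspect["summit_id"] == row["summit_id"])
                            & (by_aspect["year"] == row["year"])]
            weighted = (sub["mean"] * sub["n"]).sum() / sub["n"].sum()
            assert weighted == pytest.approx(row["mean"], rel=1e-12)
        assert (by_summit["se"] > 0).all()


class TestCoverChange:
    def test_identical_years_zero_change(self, tiny_observations):
        obs = [o for o in tiny_observations if o.species_id == "spC"]
        # spC: 5.0 in 2014, 6.0 in 2018 in quadrat 2 only
        tab = cover_change_table(obs, 2014, 2018)
        assert tab["mean_delta"].iloc[0] == pytest.approx(1.0)

    def test_uniform_gain_has_zero_se(self):
        obs = []
        for q in range(1, 17):
            obs.append(sv.QuadratObservation("GUL1", "N", q, 2014, "shrub1", 10.0))
            obs.append(sv.QuadratObservation("GUL1", "N", q, 2018, "shrub1", 12.0))
        tab = cover_change_table(obs, 2014, 2018)
        assert tab["n_quadrats"].iloc[0] == 16
        assert tab["mean_delta"].iloc[0] == pytest.approx(2.0)
        assert tab["se_delta"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_absence_counts_as_zero_cover(self):
        obs = [
            sv.QuadratObservation("GUL1", "N", 1, 2014, "spA", 8.0),
            sv.QuadratObservation("GUL1", "N", 1, 2018, "spB", 4.0),
        ]
        tab = cover_change_table(obs, 2014, 2018).set_index("species_id")
        assert tab.loc["spA", "mean_delta"] == pytest.approx(-8.0)
        assert tab.loc["spB", "mean_delta"] == pytest.approx(4.0)

    def test_grand_total_matches_cover_difference(self, default_survey):
        observations, _, _ = default_survey
        tab = cover_change_table(observations, 2014, 2018)
        grand = (tab["mean_delta"] * tab["n_quadrats"]).sum()
        total_by_year = {
            y: sum(o.cover for o in observations if o.year == y) for y in (2014, 2018)
        }
        assert grand == pytest.approx(total_by_year[2018] - total_by_year[2014], rel=1e-9)

    def test_growth_form_filter(self, default_survey):
        observations, attributes, _ = default_survey
        shrubs = {a.species_id for a in attributes if a.growth_form == "shrub"}
        tab = cover_change_table(observations, 2014, 2018,
                                 attributes=attributes, growth_form="shrub")
        assert set(tab["species_id"]) <= shrubs

    def test_recovery_of_imposed_gain(self):
        """A species given +3% mean gain with 1% noise is estimated within 3 SE."""
        rng = np.random.default_rng(8)
        means = []
        for rep in range(50):
            obs = []
            for q in range(1, 17):
                base = rng.uniform(5, 15)
                obs.append(sv.QuadratObservation("GUL1", "N", q, 2014, "sp", base))
                obs.append(sv.QuadratObservation("GUL1", "N", q, 2018, "sp",
                                                 base + rng.normal(3.0, 1.0)))
            means.append(cover_change_table(obs, 2014, 2018)["mean_delta"].iloc[0])
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 3.0) < 3 * se


class TestAnova:
    def test_all_equal_responses_give_zero_f(self):
        df = pd.DataFrame({
            "summit_id": np.repeat(["A", "B"], 8),
            "aspect": np.tile(["N", "S"], 8),
            "year": np.tile([2014, 2018], 8),
            "resp": 5.0,
        })
        tab = factor_effects(df, "resp", "twoway_interaction")
        terms = tab[tab["term"] != "Residual"]
        assert (terms["F"] == 0.0).all()

    def test_oneway_f_equals_squared_t(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "summit_id": np.repeat(["A", "B"], 4),
            "resp": np.r_[rng.normal(0, 1, 4), rng.normal(10, 1, 4)],
        })
        tab = factor_effects(df, "resp", "oneway")
        t = sps.ttest_ind(df["resp"][:4], df["resp"][4:]).statistic
        assert tab["F"].iloc[0] == pytest.approx(t**2, abs=1e-9)

    def test_nested_design_degrees_of_freedom(self, default_survey):
        observations, _, _ = default_survey
        rich = richness_per_quadrat(observations)
        rich = rich[rich["year"] == 2014]
        tab = factor_effects(rich, "richness", "oneway_nested").set_index("term")
        assert tab.loc["C(summit_id)", "df"] == 3
        assert tab.loc["C(summit_id):C(aspect)", "df"] == 12
        assert tab.loc["Residual", "df"] == 64 - 16

    def test_interaction_without_replicates_rejected(self):
        df = pd.DataFrame({
            "summit_id": np.repeat(["A", "B"], 2),
            "year": np.tile([2014, 2018], 2),
            "resp": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(DegenerateDesignError, match="replicate"):
            factor_effects(df, "resp", "twoway_interaction")

    def test_null_pvalues_uniform(self):
        """Sequential-SS one-way ANOVA p-values are uniform under the null."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(400):
            df = pd.DataFrame({
                "summit_id": np.repeat(list("ABCD"), 8),
                "resp": rng.normal(size=32),
            })
            tab = factor_effects(df, "resp", "oneway")
            pvals.append(tab["p_value"].iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestTukey:
    def test_identical_means_not_significant(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"g": np.repeat(list("abc"), 20), "y": rng.normal(size=60)})
        out = tukey_posthoc(df, "y", "g")
        assert (out["p_adj"] > 0.05).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=60)
        y[40:] += 10.0  # group c shifted by 10 within-SDs
        df = pd.DataFrame({"g": np.repeat(list("abc"), 20), "y": y})
        out = tukey_posthoc(df, "y", "g").set_index(["group1", "group2"])
        assert out.loc[("a", "c"), "p_adj"] < 0.001
        assert out.loc[("b", "c"), "p_adj"] < 0.001
        assert out.loc[("a", "b"), "p_adj"] > 0.05

    def test_adjusted_p_never_below_pooled_t(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"g": np.repeat(list("abcd"), 10), "y": rng.normal(size=40)})
        out = tukey_posthoc(df, "y", "g")
        groups = {g: grp["y"].to_numpy() for g, grp in df.groupby("g")}
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        df_resid = sum(len(v) - 1 for v in groups.values())
        for _, row in out.iterrows():
            g1, g2 = groups[row["group1"]], groups[row["group2"]]
            t = abs(g1.mean() - g2.mean()) / np.sqrt(mse * (1 / len(g1) + 1 / len(g2)))
            p_raw = 2 * sps.t.sf(t, df_resid)
            assert row["p_adj"] >= p_raw - 1e-12

    def test_singleton_level_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b", "c"], "y": [1.0, 2, 3, 4, 5]})
        with pytest.raises(DegenerateDesignError, match="c"):
            tukey_posthoc(df, "y", "g")


class TestAssumptionChecks:
    def test_gaussian_null_calibration(self):
        rng = np.random.default_rng(6)
        sw, lv = [], []
        for _ in range(300):
            df = pd.DataFrame({"g": np.repeat(list("ab"), 16), "y": rng.normal(size=32)})
            res = assumption_checks(df, "y", "g")
            sw.append(res["shapiro_p"])
            lv.append(res["levene_p"])
        assert sps.kstest(sw, "uniform").pvalue > 0.01
        assert sps.kstest(lv, "uniform").pvalue > 0.01

    def test_levene_detects_variance_ratio(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(60):
            df = pd.DataFrame({
                "g": np.repeat(list("ab"), 16),
                "y": np.r_[rng.normal(0, 1, 16), rng.normal(0, 5, 16)],
            })
            hits += assumption_checks(df, "y", "g")["levene_p"] < 0.01
        assert hits >= 54  # power >= 0.9

    def test_shapiro_detects_heavy_tails(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(100):
            df = pd.DataFrame({"g": np.repeat(list("ab"), 32), "y": rng.standard_t(2, size=64)})
            hits += assumption_checks(df, "y", "g")["shapiro_p"] < 0.05
        assert hits >= 50

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"g": list("aabb"), "y": 1.0})
        with pytest.raises(DegenerateDesignError):
            assumption_checks(df, "y", "g")


def test_total_cover_per_quadrat(tiny_observations):
    tc = total_cover_per_quadrat(tiny_observations)
    q1 = tc[(tc["quadrat_index"] == 1) & (tc["year"] == 2014)]
    assert q1["total_cover"].iloc[0] == pytest.approx(50.0)
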