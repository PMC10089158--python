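import numpy as np
import pandas as pd
import pytest

from regenfire import projection
from regenfire.dataset import ModelSpec, Term
from regenfire.projection import (Scenario, area_summary, classify_sites,
                                  partial_dependence, project_scenario)

from conftest import manual_fit


def severity_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "fire_id": [f"F{i:02d}" for i in range(n)],
        "area_m2": 100.0,
        "dist_seed_m": rng.uniform(0, 500, n),
        "tree_cover_pct": rng.uniform(0, 70, n),
        "rbr": rng.uniform(0, 800, n),
        "time_since_fire": rng.uniform(2, 12, n),
    })


SEV_SPEC = ModelSpec(terms=(Term("dist_seed_m"), Term("tree_cover_pct"),
                            Term("rbr"), Term("time_since_fire")))


class TestProjectScenario:
    def test_sign_forced_severity_ordering(self):
        tab = severity_table()
        f = manual_fit(tab, SEV_SPEC,
                       {"intercept": -4.0, "dist_seed_m": -0.8,
                        "tree_cover_pct": 0.5, "rbr": 0.0})
        p_low = project_scenario(f, tab, Scenario("low", "1981-2000"))
        p_high = project_scenario(f, tab, Scenario("high", "1981-2000"))
        assert np.all(p_low > p_high)

    def test_insensitive_model_gives_equal_probabilities(self):
        tab = severity_table()
        f = manual_fit(tab, SEV_SPEC, {"intercept": -4.0,
                                       "time_since_fire": 0.4})
        p_low = project_scenario(f, tab, Scenario("low", "2001-2020"))
        p_high = project_scenario(f, tab, Scenario("high", "2001-2020"))
        np.testing.assert_allclose(p_low, p_high, atol=1e-12)

    def test_scenario_overrides_and_fixed_conditions(self):
        tab = severity_table()
        f = manual_fit(tab, SEV_SPEC, {"intercept": -4.0,
                                       "time_since_fire": 0.4})
        sc = Scenario("low", "1981-2000")
        assert sc.time_since_fire == 10.0 and sc.area_m2 == 100.0
        assert sc.bundle == {"dist_seed_m": 10.0, "tree_cover_pct": 30.0,
                             "rbr": 100.0}
        assert Scenario("high", "1981-2000").bundle == {
            "dist_seed_m": 150.0, "tree_cover_pct": 10.0, "rbr": 400.0}

    def test_unknown_severity_or_period_rejected(self):
        with pytest.raises(ValueError):
            Scenario("medium", "1981-2000")
        with pytest.raises(ValueError):
            Scenario("low", "1990-2010")


class TestClassify:
    def test_rule_application(self):
        out = classify_sites([0.70, 0.80, 0.40], [0.30, 0.60, 0.20], 0.54)
        assert list(out["category"]) == ["likely-low-only", "likely-both",
                                         "unlikely-both"]
        assert not out["anomalous"].any()

    def test_zero_threshold_everything_likely(self):
        out = classify_sites([0.1, 0.9], [0.2, 0.8], 0.0)
        assert (out["category"] == "likely-both").all()

    def test_anomalous_sites_flagged_and_retained(self):
        with pytest.warns(UserWarning, match="ordering"):
            out = classify_sites([0.40], [0.70], 0.54)
        assert out.loc[0, "category"] == "likely-high-only"
        assert out.loc[0, "anomalous"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            classify_sites([1.2], [0.5], 0.5)


class TestAreaSummary:
    def make_map(self, cats):
        return pd.DataFrame({"category": cats})

    def test_equal_area_counting(self):
        m = self.make_map(["likely-both", "likely-both", "likely-low-only",
                           "unlikely-both"])
        out = area_summary(m)
        assert out.loc["all", "likely-both"] == 0.5
        assert out.loc["all", "likely-low-only"] == 0.25
        assert out.loc["all", "unlikely-both"] == 0.25

    def test_area_weighting(self):
        m = self.make_map(["likely-both", "unlikely-both"])
        out = area_summary(m, cell_area=np.array([1.0, 3.0]))
        assert out.loc["all", "likely-both"] == 0.25
        assert out.loc["all", "unlikely-both"] == 0.75

    def test_proportions_sum_to_one_per_region(self, rng):
        cats = rng.choice(["likely-both", "likely-low-only", "unlikely-both"],
                          size=200)
        reg = rng.choice(["N", "S"], size=200)
        area = rng.uniform(0.5, 3.0, size=200)
        out = area_summary(self.make_map(cats), region=reg, cell_area=area)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-10)

    def test_split_cell_invariance(self):
        m = self.make_map(["likely-both", "unlikely-both"])
        a = area_summary(m, cell_area=np.array([2.0, 2.0]))
        m2 = self.make_map(["likely-both", "likely-both", "unlikely-both"])
        b = area_summary(m2, cell_area=np.array([1.0, 1.0, 2.0]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            area_summary(self.make_map([]))


class TestPartialDependence:
    def test_null_focal_effect_gives_flat_curve(self):
        tab = severity_table(60)
        f = manual_fit(tab, SEV_SPEC, {"intercept": -2.0,
                                       "tree_cover_pct": 0.5})
        pdp = partial_dependence(f, tab, focal="dist_seed_m", draws=250,
                                 grid=20)
        assert pdp["prob"].std() < 1e-12

    def test_no_interaction_percentile_curves_coincide(self):
        # with no dependence on the named interacting covariate at all,
        # the three percentile curves are identical
        tab = severity_table(60)
        f = manual_fit(tab, SEV_SPEC, {"intercept": -2.0, "dist_seed_m": -0.7})
        pdp = partial_dependence(f, tab, focal="dist_seed_m",
                                 interacting="rbr", draws=250, grid=15)
        wide = pdp.pivot_table(index="x", columns="interacting_level",
                               values="prob")
        np.testing.assert_allclose(wide["p10"], wide["p50"], atol=1e-12)
        np.testing.assert_allclose(wide["p50"], wide["p90"], atol=1e-12)

    def test_no_interaction_term_curves_parallel_on_logit_scale(self):
        # a main effect without an interaction shifts curves by a constant
        # on the logit scale (separability); an interaction would not
        tab = severity_table(60)
        f = manual_fit(tab, SEV_SPEC, {"intercept": -2.0, "dist_seed_m": -0.7,
                                       "rbr": -0.3})
        pdp = partial_dependence(f, tab, focal="dist_seed_m",
                                 interacting="rbr", draws=250, grid=15)
        wide = pdp.pivot_table(index="x", columns="interacting_level",
                               values="prob")
        logit = lambda p: np.log(p / (1 - p))
        gap = logit(wide["p10"]) - logit(wide["p90"])
        np.testing.assert_allclose(gap, gap.iloc[0], atol=1e-10)

    def test_curve_center_equals_plugin_formula(self):
        from scipy.special import expit
        tab = severity_table(50)
        coef = {"intercept": -2.0, "dist_seed_m": -0.7, "tree_cover_pct": 0.4}
        f = manual_fit(tab, SEV_SPEC, coef)
        pdp = partial_dependence(f, tab, focal="dist_seed_m", draws=250,
                                 grid=25)
        mu, sd = f.scaler["dist_seed_m"]
        z = (pdp["x"].to_numpy() - mu) / sd
        zc = (tab["tree_cover_pct"].median() - f.scaler["tree_cover_pct"][0]) \
            / f.scaler["tree_cover_pct"][1]
        zt = (tab["time_since_fire"].median() - f.scaler["time_since_fire"][0]) \
            / f.scaler["time_since_fire"][1]
        zr = (tab["rbr"].median() - f.scaler["rbr"][0]) / f.scaler["rbr"][1]
        eta = (-2.0 - 0.7 * z + 0.4 * zc + 0.0 * zt + 0.0 * zr
               + np.log(tab["area_m2"].median()))
        np.testing.assert_allclose(pdp["prob"], expit(eta), atol=1e-10)

    def test_categorical_focal_gives_per_level_estimates(self):
        tab = severity_table(60)
        tab["disturbance"] = np.tile(["none", "wildfire", "blowdown"], 20)
        spec = ModelSpec(terms=SEV_SPEC.terms
                         + (Term("disturbance", categorical=True),))
        f = manual_fit(tab, spec, {"intercept": -2.0,
                                   "disturbance[wildfire]": -0.8})
        pdp = partial_dependence(f, tab, focal="disturbance", draws=250)
        assert len(pdp) == 3
        probs = dict(zip(pdp["x"], pdp["prob"]))
        assert probs["wildfire"] < probs["none"]

    def test_too_few_draws_rejected(self):
        tab = severity_table(20)
        f = manual_fit(tab, SEV_SPEC, {})
        with pytest.raises(ValueError, match="draws"):
            partial_dependence(f, tab, focal="rbr", draws=50)
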