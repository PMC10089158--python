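import numpy as np
import pandas as pd
import pytest

from regenfire import dataset
from regenfire.dataset import ModelSpec, Term


def toy_raw_table():
    """Six plots: 1 unburned control, 1 planted, 1 prefiltered fire year,
    1 surveyed too soon, 2 valid."""
    return pd.DataFrame({
        "plot_id": list("abcdef"),
        "burned": [False, True, True, True, True, True],
        "planted": [False, True, False, False, False, False],
        "fire_year": [2000, 2000, 1980, 2000, 2005, 2010],
        "survey_year": [2005, 2005, 1985, 2001, 2010, 2015],
    })


class TestInclusionFilters:
    def test_toy_table_exclusions_itemized(self):
        kept, log = dataset.apply_inclusion_filters(toy_raw_table())
        assert sorted(kept["plot_id"]) == ["e", "f"]
        assert log == {"unburned_control": 1, "planted": 1,
                       "fire_year_out_of_range": 1,
                       "surveyed_lt_2y_postfire": 1}
        assert sum(log.values()) == 6 - len(kept)

    def test_all_valid_is_noop_and_idempotent(self):
        valid = toy_raw_table().iloc[[4, 5]].reset_index(drop=True)
        kept, log = dataset.apply_inclusion_filters(valid)
        pd.testing.assert_frame_equal(kept, valid)
        again, log2 = dataset.apply_inclusion_filters(kept)
        pd.testing.assert_frame_equal(again, kept)
        assert sum(log2.values()) == 0

    def test_empty_table(self):
        kept, log = dataset.apply_inclusion_filters(toy_raw_table().iloc[:0])
        assert len(kept) == 0
        assert sum(log.values()) == 0

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="planted"):
            dataset.apply_inclusion_filters(
                toy_raw_table().drop(columns=["planted"]))


class TestModelSpec:
    def test_interaction_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="hierarchy"):
            ModelSpec(terms=(Term("a"),), interactions=(("a", "b"),))

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            ModelSpec(terms=(Term("a"), Term("a")))

    def test_removable_excludes_biophysical_and_interaction_parents(self):
        spec = ModelSpec(terms=(Term("rbr"),
                                Term("m", role="climate_mean"),
                                Term("z", role="climate_post")),
                         interactions=(("m", "z"),))
        assert spec.removable_terms() == []
        assert spec.drop_interaction(("m", "z")).removable_terms() == ["m", "z"]

    def test_roundtrips_through_dict(self):
        spec = ModelSpec(terms=(Term("a", quadratic=True),
                                Term("d", categorical=True),
                                Term("z", role="climate_post")),
                         interactions=(), variety=True)
        assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestBuildDesign:
    def base_table(self):
        return pd.DataFrame({
            "presence": [0, 1, 1],
            "fire_id": ["f1", "f1", "f2"],
            "area_m2": [100.0, 50.0, 200.0],
            "a": [1.0, 2.0, 3.0],
            "b": [5.0, 3.0, 1.0],
        })

    def test_intercept_only(self):
        d = dataset.build_design(self.base_table(), ModelSpec())
        assert list(d.X.columns) == ["intercept"]
        np.testing.assert_allclose(d.offset, np.log([100.0, 50.0, 200.0]))

    def test_standardization_uses_sample_sd(self):
        d = dataset.build_design(self.base_table(),
                                 ModelSpec(terms=(Term("a"),)))
        np.testing.assert_allclose(d.X["a"], [-1.0, 0.0, 1.0])

    def test_interaction_is_product_of_standardized_columns(self):
        spec = ModelSpec(terms=(Term("a"), Term("b")),
                         interactions=(("a", "b"),))
        d = dataset.build_design(self.base_table(), spec)
        np.testing.assert_allclose(d.X["a:b"], d.X["a"] * d.X["b"])

    def test_quadratic_from_standardized_values(self):
        d = dataset.build_design(self.base_table(),
                                 ModelSpec(terms=(Term("a", quadratic=True),)))
        np.testing.assert_allclose(d.X["a^2"], d.X["a"] ** 2)

    def test_zero_variance_covariate_rejected(self):
        tab = self.base_table().assign(a=1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            dataset.build_design(tab, ModelSpec(terms=(Term("a"),)))

    def test_unresolvable_term_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            dataset.build_design(self.base_table(),
                                 ModelSpec(terms=(Term("ghost"),)))

    def test_categorical_reference_is_none_level(self):
        tab = self.base_table().assign(
            disturbance=["none", "wildfire", "blowdown"])
        d = dataset.build_design(
            tab, ModelSpec(terms=(Term("disturbance", categorical=True),)))
        assert "disturbance[none]" not in d.X.columns
        assert "disturbance[wildfire]" in d.X.columns

    def test_train_scaler_applied_and_unseen_level_rejected(self):
        tab = self.base_table().assign(disturbance=["none", "none", "wildfire"])
        spec = ModelSpec(terms=(Term("a"), Term("disturbance", categorical=True)))
        d = dataset.build_design(tab, spec)
        new = tab.copy()
        d2 = dataset.build_design(new, spec, scaler=d.scaler,
                                  require_response=False)
        np.testing.assert_allclose(d2.X["a"], d.X["a"])
        new.loc[0, "disturbance"] = "beetle outbreak"
        with pytest.raises(ValueError, match="unseen"):
            dataset.build_design(new, spec, scaler=d.scaler,
                                 require_response=False)


def test_standardization_roundtrip_reproduces_probabilities():
    """Raw-scale back-transformed coefficients give identical predictions."""
    from scipy.special import expit
    from conftest import simulate_plot_table, manual_fit
    tab = simulate_plot_table(10, 20, {"intercept": -1.0, "x": 0.8},
                              sigma=0.0, seed=1)
    spec = ModelSpec(terms=(Term("x"),))
    from regenfire import glmm
    fitted = glmm.fit_glmm(tab, spec)
    raw = fitted.coef_raw_scale()
    eta_raw = (raw["intercept"] + raw["x"] * tab["x"]
               + np.log(tab["area_m2"]))
    p_raw = expit(eta_raw)
    p_std = glmm.predict_probability(fitted, tab, level="population")
    np.testing.assert_allclose(p_raw, p_std, atol=1e-10)


class TestCollinearityScreen:
    def test_identical_columns_flagged_r1(self):
        x = np.random.default_rng(1).normal(size=50)
        X = pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(2).normal(size=50)})
        rep = dataset.collinearity_screen(X)
        pairs = [(p[0], p[1]) for p in rep["pairs"]]
        assert ("a", "b") in pairs
        assert rep["pairs"][0][2] == pytest.approx(1.0)

    def test_orthogonal_columns_unflagged_unit_vif(self):
        n = 40
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rep = dataset.collinearity_screen(pd.DataFrame({"a": a, "b": b}))
        assert rep["pairs"] == [] and rep["flagged_vif"] == []
        assert rep["vif"]["a"] == pytest.approx(1.0)

    def test_r08_pair_gives_closed_form_vif(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        e = rng.normal(size=200)
        # orthogonalize then mix for an exact sample correlation of 0.8
        a = (a - a.mean()) / a.std(ddof=1)
        e = e - e.mean() - a * np.cov(a, e, ddof=1)[0, 1] / a.var(ddof=1)
        e = e / e.std(ddof=1)
        b = 0.8 * a + np.sqrt(1 - 0.64) * e
        rep = dataset.collinearity_screen(pd.DataFrame({"a": a, "b": b}))
        assert rep["vif"]["a"] == pytest.approx(1.0 / (1 - 0.64), abs=1e-6)
        assert len(rep["pairs"]) == 1  # flagged by the correlation rule
        assert rep["flagged_vif"] == []  # VIF 2.78 < 5

    def test_auto_drop_keeps_earlier_priority(self):
        x = np.random.default_rng(4).normal(size=30)
        rep = dataset.collinearity_screen(
            pd.DataFrame({"keep": x, "drop": x + 1e-9}),
            priority=["keep", "drop"], auto_drop=True)
        assert rep["dropped"] == ["drop"]
        assert rep["retained"] == ["keep"]

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dataset.collinearity_screen(
                pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)}))
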