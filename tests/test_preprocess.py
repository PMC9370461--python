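"""Trait corrections, transforms, exclusions and predictor filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from senspi.preprocess import (
    MedicationConstants,
    energy_adjust_residual,
    fil_exclusion,
    filter_predictors,
    friedewald_ldl,
    inverse_normal_transform,
    medication_correction,
    outlier_removal,
    vif_filter,
)


class TestMedicationCorrection:
    def make_visit(self, **over):
        base = dict(sbp=[120.0], dbp=[80.0], tc=[5.0], tg=[1.0], hdl=[1.3],
                    ldl=[3.0], on_bp_med=[True], on_lipid_med=[True])
        base.update(over)
        return pd.DataFrame(base)

    def test_bp_offsets(self):
        out = medication_correction(self.make_visit())
        assert out.loc[0, "sbp"] - 120.0 == pytest.approx(15.0)
        assert out.loc[0, "dbp"] - 80.0 == pytest.approx(10.0)

    def test_lipid_offsets(self):
        out = medication_correction(self.make_visit())
        assert out.loc[0, "tg"] == pytest.approx(1.208)
        assert out.loc[0, "tc"] == pytest.approx(6.347)
        assert out.loc[0, "hdl"] == pytest.approx(1.240)
        assert out.loc[0, "ldl"] == pytest.approx(4.290)

    def test_untreated_unchanged(self):
        v = self.make_visit(on_bp_med=[False], on_lipid_med=[False])
        out = medication_correction(v)
        pd.testing.assert_frame_equal(out[["sbp", "dbp", "tc", "tg", "hdl", "ldl"]],
                                      v[["sbp", "dbp", "tc", "tg", "hdl", "ldl"]])

    def test_missing_flag_treated_as_untreated(self):
        v = self.make_visit(on_bp_med=[np.nan])
        out = medication_correction(v)
        assert out.loc[0, "sbp"] == 120.0

    def test_double_application_guarded(self):
        out = medication_correction(self.make_visit())
        with pytest.raises(ValueError):
            medication_correction(out)


class TestFriedewald:
    def test_worked_example(self):
        assert friedewald_ldl(5.2, 1.0, 2.2) == pytest.approx(3.2)

    def test_zero_tg_limit(self):
        assert friedewald_ldl(5.0, 1.2, 0.0) == pytest.approx(3.8)

    def test_high_tg_invalid(self):
        assert np.isnan(friedewald_ldl(5.0, 1.0, 5.0))
        assert np.isnan(friedewald_ldl(5.0, 1.0, 4.52))

    def test_vectorized(self):
        out = friedewald_ldl([5.2, 5.0], [1.0, 1.0], [2.2, 5.0])
        assert out[0] == pytest.approx(3.2) and np.isnan(out[1])


class TestInverseNormal:
    def test_blom_oracle_three_values(self):
        # [5,1,3] -> ranks (3,1,2); Blom scores (r-3/8)/(3+1/4) =
        # (21/26, 5/26, 1/2); Phi^{-1} of those = (0.86942, -0.86942, 0)
        out = inverse_normal_transform([5.0, 1.0, 3.0])
        assert out == pytest.approx([0.86942, -0.86942, 0.0], abs=1e-4)

    def test_middle_of_odd_vector_is_zero(self):
        out = inverse_normal_transform([10.0, 2.0, 5.0, 7.0, 1.0])
        assert out[np.argsort([10.0, 2.0, 5.0, 7.0, 1.0])[2]] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=40, unique=True))
    def test_rank_invariance_under_monotone_transform(self, xs):
        x = np.array(xs, dtype=float)
        a = inverse_normal_transform(x)
        b = inverse_normal_transform(np.exp(x / 2e6) * 3 + 1)
        assert np.allclose(a, b)

    def test_output_mean_zero_and_normal(self):
        x = np.random.default_rng(3).exponential(2.0, 800)
        z = inverse_normal_transform(x)
        assert abs(z.mean()) < 1e-10
        assert stats.normaltest(z).pvalue > 0.01
        assert np.array_equal(np.argsort(z), np.argsort(x))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([2.0, 2.0, 2.0])

    def test_missing_values_propagate(self):
        out = inverse_normal_transform([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(out[1]) and not np.isnan(out[[0, 2, 3]]).any()


class TestEnergyAdjustment:
    def test_proportional_nutrient_becomes_constant(self):
        tei = np.linspace(1500, 3000, 50)
        nutrient = 0.4 * tei
        adj = energy_adjust_residual(nutrient, tei)
        assert np.allclose(adj, nutrient.mean())

    def test_orthogonality_and_mean_preserved(self):
        rng = np.random.default_rng(4)
        tei = rng.normal(2200, 300, 500)
        nutrient = 0.1 * tei + rng.normal(0, 20, 500)
        adj = energy_adjust_residual(nutrient, tei)
        assert abs(np.corrcoef(adj, tei)[0, 1]) < 1e-10
        assert adj.mean() == pytest.approx(nutrient.mean())

    def test_independent_nutrient_nearly_unchanged(self):
        rng = np.random.default_rng(5)
        tei = rng.normal(2200, 300, 5000)
        nutrient = rng.normal(50, 10, 5000)
        adj = energy_adjust_residual(nutrient, tei)
        assert np.corrcoef(adj, nutrient)[0, 1] > 0.999

    def test_constant_tei_rejected(self):
        with pytest.raises(ValueError):
            energy_adjust_residual(np.arange(10.0), np.full(10, 2000.0))


class TestFilExclusion:
    def test_expected_exclusion_count(self):
        fil_base = np.random.default_rng(6).normal(1.5, 0.3, 1000)
        keep = fil_exclusion(fil_base * 1600.0, np.full(1000, 1600.0))
        assert 1000 - keep.sum() == pytest.approx(75, abs=2)

    def test_median_subject_kept(self):
        tei = np.random.default_rng(7).normal(2200, 300, 200)
        bmr = np.full(200, 1500.0)
        keep = fil_exclusion(tei, bmr)
        med = np.argsort(tei)[100]
        assert keep[med]

    def test_identical_fil_excludes_none(self):
        keep = fil_exclusion(np.full(100, 2000.0), np.full(100, 1500.0))
        assert keep.all()

    def test_small_cohort_warns(self):
        with pytest.warns(UserWarning):
            fil_exclusion(np.random.default_rng(8).normal(2000, 100, 20),
                          np.full(20, 1500.0))


class TestPredictorFilters:
    def test_duplicate_column_one_removed(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(200)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(200)})
        kept = filter_predictors(X)
        assert len([c for c in kept if c in ("a", "b")]) == 1 and "c" in kept

    def test_constant_column_removed(self):
        X = pd.DataFrame({"a": np.arange(50.0), "z": np.ones(50)})
        assert "z" not in filter_predictors(X)

    def test_independent_columns_all_kept(self):
        X = pd.DataFrame(np.random.default_rng(10).standard_normal((1000, 8)))
        X.columns = [f"c{j}" for j in range(8)]
        assert len(filter_predictors(X)) == 8

    def test_postcondition_all_pairwise_below_threshold(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((300, 1))
        X = pd.DataFrame(0.95 * z + 0.3 * rng.standard_normal((300, 6)),
                         columns=[f"c{j}" for j in range(6)])
        kept = filter_predictors(X, 0.80)
        corr = X[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.80

    def test_vif_orthogonal_all_kept(self):
        X = pd.DataFrame(np.random.default_rng(12).standard_normal((500, 5)),
                         columns=list("abcde"))
        assert vif_filter(X) == list("abcde")

    def test_vif_exact_collinearity_removed_first(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        X = pd.DataFrame({"a": a, "b": b, "s": a + b})
        kept = vif_filter(X)
        assert len(kept) == 2

    def test_vif_strong_ar1_triggers_removal(self):
        rng = np.random.default_rng(14)
        n, p, rho = 800, 5, 0.99
        Z = rng.standard_normal((n, p))
        X = np.zeros((n, p))
        X[:, 0] = Z[:, 0]
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + np.sqrt(1 - rho**2) * Z[:, j]
        kept = vif_filter(pd.DataFrame(X, columns=[f"c{j}" for j in range(p)]))
        assert len(kept) < p


class TestOutlierRemoval:
    def test_out_of_bounds_set_missing(self):
        v = pd.DataFrame({"sbp": [120.0, 400.0]})
        out = outlier_removal(v, {"sbp": (60.0, 250.0)})
        assert np.isnan(out.loc[1, "sbp"]) and out.loc[0, "sbp"] == 120.0

    def test_within_bounds_unchanged(self):
        v = pd.DataFrame({"sbp": [100.0, 180.0]})
        out = outlier_removal(v, {"sbp": (60.0, 250.0)})
        pd.testing.assert_frame_equal(out, v)

    def test_boundary_value_kept(self):
        v = pd.DataFrame({"sbp": [250.0, 60.0]})
        out = outlier_removal(v, {"sbp": (60.0, 250.0)})
        assert not out["sbp"].isna().any()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            outlier_removal(pd.DataFrame({"sbp": [120.0]}), {"sbp": (250.0, 60.0)})


def test_medication_constants_defaults():
    c = MedicationConstants()
    assert (c.tg_add, c.tc_add, c.hdl_add, c.ldl_add, c.sbp_add, c.dbp_add) == (
        0.208, 1.347, -0.060, 1.290, 15.0, 10.0)
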