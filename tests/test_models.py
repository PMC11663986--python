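"""Elastic-net bootstraps, RSF ensembles, consensus, final Cox."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cardiodose.exceptions import ConfigurationError, DataError
from cardiodose.models import (
    ImportanceSummary,
    ModelRunConfig,
    SelectionSummary,
    bootstrap_elastic_net,
    confounder_design,
    consensus_selection,
    cox_log_partial_likelihood,
    final_multivariable_cox,
    rsf_ensemble,
    screen_confounders,
    univariable_cox,
)
from cardiodose.synth import (
    CensoringSpec,
    HazardSpec,
    generate_feature_cohort,
    recovery_hazard,
)


@pytest.fixture(scope="module")
def driver_cohort():
    return generate_feature_cohort(250, 31, hazard=recovery_hazard())


def small_config(**kw):
    defaults = dict(n_boot=15, n_forests=2, n_trees=80, cv_folds=3,
                    alpha_grid=(0.0, 0.5, 1.0), n_penalties=6, seed=4)
    defaults.update(kw)
    return ModelRunConfig(**defaults)


class TestUnivariableCox:
    def test_recovers_known_effect(self, driver_cohort):
        res = univariable_cox(driver_cohort["LA_mean_eqd2"],
                              driver_cohort["survival_days"],
                              driver_cohort["event"], name="la")
        assert res.ci_low <= res.hazard_ratio <= res.ci_high
        assert res.hazard_ratio > 1.0
        assert res.p_value < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError, match="variance"):
            univariable_cox(np.ones(30), np.arange(1, 31),
                            np.ones(30, dtype=int))

    def test_tied_times_finite_result(self):
        t = np.repeat([5.0, 10.0, 15.0], 8)
        e = np.ones(24, dtype=int)
        x = np.tile([0.0, 1.0], 12)
        res = univariable_cox(x, t, e)
        assert np.isfinite(res.hazard_ratio)
        assert np.isfinite(res.p_value)


class TestPartialLikelihood:
    def test_matches_lifelines_at_fitted_coefficients(self, rng):
        X = rng.normal(size=(60, 3))
        t = rng.exponential(20, 60)
        e = (rng.random(60) < 0.6).astype(int)
        df = pd.DataFrame(X, columns=list("abc"))
        df["t"], df["e"] = t, e
        cph = CoxPHFitter().fit(df, "t", "e")
        mine = cox_log_partial_likelihood(X, t, e, cph.params_.to_numpy())
        assert mine == pytest.approx(cph.log_likelihood_, rel=1e-10)


class TestConfounderScreen:
    def test_true_confounder_kept_null_dropped(self):
        hz = HazardSpec(
            log_hazard_coefficients={"LA_mean_eqd2": 0.0, "age": 0.06},
            reference_values={"age": 73.0}, driver_feature="LA_mean_eqd2")
        co = generate_feature_cohort(500, 13, hazard=hz)
        design, groups = confounder_design(co)
        retained = screen_confounders(design, groups, co["survival_days"],
                                      co["event"])
        assert "age" in retained
        assert "stage" not in retained

    def test_empty_candidates(self, driver_cohort):
        out = screen_confounders(pd.DataFrame(index=driver_cohort.index), {},
                                 driver_cohort["survival_days"],
                                 driver_cohort["event"])
        assert out == []


class TestElasticNet:
    def test_pure_ridge_selects_everything(self, driver_cohort):
        dose = driver_cohort[[c for c in driver_cohort.columns
                              if c.endswith("_eqd2")]].iloc[:, :8]
        cfg = small_config(alpha_grid=(0.0,), n_boot=5)
        out = bootstrap_elastic_net(dose, driver_cohort["survival_days"],
                                    driver_cohort["event"], cfg)
        assert (out.selection_pct == 100.0).all()
        assert out.mean_tuned_alpha == 0.0

    def test_driver_has_top_selection(self, driver_cohort):
        dose = driver_cohort[[c for c in driver_cohort.columns
                              if c.endswith("_eqd2")]]
        cfg = small_config(n_boot=20)
        out = bootstrap_elastic_net(dose, driver_cohort["survival_days"],
                                    driver_cohort["event"], cfg)
        assert out.selection_pct.idxmax() == "LA_mean_eqd2"

    def test_deterministic_given_seed(self, driver_cohort):
        dose = driver_cohort[[c for c in driver_cohort.columns
                              if c.endswith("_eqd2")]].iloc[:, :6]
        cfg = small_config(n_boot=4)
        a = bootstrap_elastic_net(dose, driver_cohort["survival_days"],
                                  driver_cohort["event"], cfg)
        b = bootstrap_elastic_net(dose, driver_cohort["survival_days"],
                                  driver_cohort["event"], cfg)
        pd.testing.assert_series_equal(a.selection_pct, b.selection_pct)
        assert a.mean_tuned_alpha == b.mean_tuned_alpha

    def test_too_few_events_rejected(self, driver_cohort):
        dose = driver_cohort[["LA_mean_eqd2"]].iloc[:20]
        events = pd.Series(np.zeros(20, dtype=int))
        events.iloc[:3] = 1
        with pytest.raises(DataError):
            bootstrap_elastic_net(dose, driver_cohort["survival_days"].iloc[:20],
                                  events, small_config(cv_folds=5))


class TestRsfEnsemble:
    def test_driver_tops_importance(self, driver_cohort):
        dose = driver_cohort[[c for c in driver_cohort.columns
                              if c.endswith("_eqd2")]]
        cfg = small_config(n_forests=3, n_trees=120)
        out = rsf_ensemble(dose, driver_cohort["survival_days"],
                           driver_cohort["event"], cfg)
        assert out.median_importance.idxmax() == "LA_mean_eqd2"
        assert out.median_importance["LA_mean_eqd2"] > 0.0

    def test_invalid_forest_count(self):
        with pytest.raises(ConfigurationError):
            small_config(n_forests=0)

    def test_duplicated_column_dilutes_importance(self, driver_cohort):
        dose = driver_cohort[["LA_mean_eqd2", "RV_mean_eqd2", "SVC_max_eqd2"]]
        cfg = small_config(n_forests=3, n_trees=120)
        single = rsf_ensemble(dose, driver_cohort["survival_days"],
                              driver_cohort["event"], cfg)
        doubled = dose.copy()
        doubled["LA_mean_copy"] = dose["LA_mean_eqd2"]
        dup = rsf_ensemble(doubled, driver_cohort["survival_days"],
                           driver_cohort["event"], cfg)
        assert (dup.median_importance["LA_mean_eqd2"]
                < single.median_importance["LA_mean_eqd2"])


class TestConsensus:
    def _summaries(self, pct_runs, vimp_runs, threshold=0.01):
        cfg = small_config()
        en = [SelectionSummary(cfg, pd.Series(p), 0.3) for p in pct_runs]
        rsf = [ImportanceSummary(cfg, pd.Series(v),
                                 pd.Series(v) > threshold) for v in vimp_runs]
        return en, rsf

    def test_unanimous_winner(self):
        pct = [{"a_mean_eqd2": 90.0, "b_max_eqd2": 60.0}] * 3
        vimp = [{"a_mean_eqd2": 0.03, "b_max_eqd2": 0.002}] * 3
        en, rsf = self._summaries(pct, vimp)
        assert consensus_selection(en, rsf) == ["a_mean_eqd2"]

    def test_conjunction_excludes_on_single_rsf_failure(self):
        pct = [{"a_mean_eqd2": 90.0, "b_max_eqd2": 60.0}] * 3
        vimp = [{"a_mean_eqd2": 0.03, "b_max_eqd2": 0.002}] * 2 + [
            {"a_mean_eqd2": 0.005, "b_max_eqd2": 0.002}]
        en, rsf = self._summaries(pct, vimp)
        assert consensus_selection(en, rsf) == []

    def test_tolerance_band_admits_near_top(self):
        pct = [{"a_mean_eqd2": 90.0, "b_mean_eqd2": 88.0}] * 2
        vimp = [{"a_mean_eqd2": 0.03, "b_mean_eqd2": 0.02}] * 2
        en, rsf = self._summaries(pct, vimp)
        assert set(consensus_selection(en, rsf)) == {"a_mean_eqd2",
                                                     "b_mean_eqd2"}

    def test_invariant_to_feature_order(self):
        pct = [{"a_mean_eqd2": 90.0, "b_max_eqd2": 60.0, "c_max_eqd2": 30.0}]
        vimp = [{"a_mean_eqd2": 0.03, "b_max_eqd2": 0.002, "c_max_eqd2": 0.0}]
        en, rsf = self._summaries(pct, vimp)
        rev_pct = [dict(reversed(list(pct[0].items())))]
        rev_vimp = [dict(reversed(list(vimp[0].items())))]
        en2, rsf2 = self._summaries(rev_pct, rev_vimp)
        assert consensus_selection(en, rsf) == consensus_selection(en2, rsf2)


class TestFinalCox:
    def test_reduces_to_univariable_without_confounders(self, driver_cohort):
        res = final_multivariable_cox(driver_cohort, "LA_mean_eqd2", [],
                                      driver_cohort["survival_days"],
                                      driver_cohort["event"])
        uni = univariable_cox(driver_cohort["LA_mean_eqd2"],
                              driver_cohort["survival_days"],
                              driver_cohort["event"], name="LA_mean_eqd2")
        assert res[0].hazard_ratio == pytest.approx(uni.hazard_ratio, rel=1e-8)

    def test_rescaling_dose_rescales_log_hr(self, driver_cohort):
        data = driver_cohort[["LA_mean_eqd2", "age"]].copy()
        r1 = final_multivariable_cox(data, "LA_mean_eqd2", ["age"],
                                     driver_cohort["survival_days"],
                                     driver_cohort["event"])
        data2 = data.copy()
        data2["LA_mean_eqd2"] = data2["LA_mean_eqd2"] * 100.0  # Gy -> cGy
        r2 = final_multivariable_cox(data2, "LA_mean_eqd2", ["age"],
                                     driver_cohort["survival_days"],
                                     driver_cohort["event"])
        assert math.log(r2[0].hazard_ratio) == pytest.approx(
            math.log(r1[0].hazard_ratio) / 100.0, rel=1e-6)
        assert r2[0].p_value == pytest.approx(r1[0].p_value, rel=1e-6)

    def test_collinear_design_rejected(self, driver_cohort):
        data = driver_cohort[["LA_mean_eqd2"]].copy()
        data["dup"] = data["LA_mean_eqd2"]
        with pytest.raises(DataError, match="condition"):
            final_multivariable_cox(data, "LA_mean_eqd2", ["dup"],
                                    driver_cohort["survival_days"],
                                    driver_cohort["event"])

    def test_recovers_designed_hazard_ratio(self, driver_cohort):
        design, groups = confounder_design(driver_cohort)
        data = driver_cohort[["LA_mean_eqd2"]].join(design[["age", "sex_M"]])
        res = final_multivariable_cox(data, "LA_mean_eqd2", ["age", "sex_M"],
                                      driver_cohort["survival_days"],
                                      driver_cohort["event"])
        hr = res[0]
        log_se = (math.log(hr.ci_high) - math.log(hr.ci_low)) / (2 * 1.959964)
        assert abs(math.log(hr.hazard_ratio) - math.log(1.05)) <= 2 * log_se
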