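"""Synthetic cohort generator: phantom, dose, covariates, survival."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiodose.exceptions import ConfigurationError, DataError, GeometryError
from cardiodose.synth import (
    CensoringSpec,
    CohortSpec,
    HazardSpec,
    cohort_to_frame,
    generate_cohort,
    generate_dose_grid,
    generate_feature_cohort,
    rasterize_masks,
    recovery_hazard,
    simulate_survival,
)


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(n_patients=6, seed=11)
    records, geoms = generate_cohort(spec)
    return spec, records, geoms


class TestCohortSpec:
    def test_zero_patients_rejected(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            CohortSpec(n_patients=0).validate()

    def test_bad_mix_rejected(self):
        spec = CohortSpec(fractionation_mix={(3, 18.0): 0.5, (5, 12.0): 0.6})
        with pytest.raises(ConfigurationError, match="fractionation_mix"):
            spec.validate()

    def test_driver_must_have_coefficient(self):
        hz = HazardSpec(log_hazard_coefficients={"age": 0.1}, driver_feature="x")
        with pytest.raises(ConfigurationError, match="driver"):
            hz.validate()


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        spec = CohortSpec(n_patients=4, seed=3)
        df1 = cohort_to_frame(generate_cohort(spec)[0])
        df2 = cohort_to_frame(generate_cohort(spec)[0])
        pd.testing.assert_frame_equal(df1, df2)
        assert df1.to_csv() == df2.to_csv()

    def test_patient_substreams_stable_under_cohort_growth(self):
        a = cohort_to_frame(generate_cohort(CohortSpec(n_patients=3, seed=9))[0])
        b = cohort_to_frame(generate_cohort(CohortSpec(n_patients=6, seed=9))[0])
        pd.testing.assert_frame_equal(a, b.iloc[:3])


class TestCovariateMarginals:
    def test_male_fraction(self):
        # target proportion 0.564; n=6000 gives binomial SD ~0.0064
        df = generate_feature_cohort(6000, 123)
        male = (df["sex"] == "M").mean()
        assert abs(male - 0.564) < 3 * math.sqrt(0.564 * 0.436 / 6000)

    def test_volumes_ordered(self):
        df = generate_feature_cohort(500, 7)
        assert (df["ptv_cc"] >= df["gtv_cc"]).all()
        assert (df["gtv_cc"] > 0).all()


class TestPhantomMasks:
    def test_mask_algebra(self, small_cohort):
        _, _, geoms = small_cohort
        for geom in geoms[:3]:
            m = rasterize_masks(geom)
            chambers = [m[k].voxels for k in ("LA", "LV", "RA", "RV")]
            for i in range(4):
                for j in range(i + 1, 4):
                    assert not (chambers[i] & chambers[j]).any()
                assert not (chambers[i] & ~m["WH"].voxels).any()
            lungs = m["LL"].voxels | m["RL"].voxels
            assert not (lungs & m["WH"].voxels).any()
            for mask in m.values():
                assert mask.voxels.any()

    def test_degenerate_structure_raises(self, small_cohort):
        from dataclasses import replace

        _, _, geoms = small_cohort
        geom = replace(geoms[0], ptv_radii=(0.4, 0.4, 0.4), gtv_radii=(0.3, 0.3, 0.3))
        with pytest.raises(GeometryError):
            rasterize_masks(geom)


class TestDoseGrid:
    def test_plateau_is_exact_prescription(self, small_cohort):
        spec, records, geoms = small_cohort
        rec, geom = records[0], geoms[0]
        rx = rec.n_fractions * rec.dose_per_fraction
        ptv = rasterize_masks(geom, structures=["PTV"])["PTV"]
        dose = generate_dose_grid(geom, rx, spec.dose_falloff_mm,
                                  rec.n_fractions, ptv_mask=ptv)
        assert dose.values[ptv.voxels].mean() == rx
        assert (dose.values >= 0).all()

    def test_monotone_falloff_with_distance(self, small_cohort):
        from scipy import ndimage

        spec, records, geoms = small_cohort
        geom = geoms[0]
        ptv = rasterize_masks(geom, structures=["PTV"])["PTV"]
        dose = generate_dose_grid(geom, 60.0, spec.dose_falloff_mm, 3, ptv_mask=ptv)
        dt = ndimage.distance_transform_edt(~ptv.voxels, sampling=geom.spacing)
        near = dose.values[(dt > 8) & (dt < 12)]
        far = dose.values[(dt > 28) & (dt < 32)]
        assert near.min() >= far.max()

    def test_shorter_falloff_lowers_exterior_dose(self, small_cohort):
        _, records, geoms = small_cohort
        geom = geoms[0]
        ptv = rasterize_masks(geom, structures=["PTV"])["PTV"]
        d1 = generate_dose_grid(geom, 60.0, 16.0, 3, ptv_mask=ptv)
        d2 = generate_dose_grid(geom, 60.0, 8.0, 3, ptv_mask=ptv)
        outside = ~ptv.voxels
        assert (d2.values[outside] <= d1.values[outside] + 1e-12).all()


class TestSurvivalGenerator:
    def test_baseline_matches_weibull_survivor_function(self):
        # zero coefficients, no censoring: KM estimate ~ closed-form Weibull
        n = 5000
        hz = HazardSpec(log_hazard_coefficients={"x": 0.0}, driver_feature="x",
                        reference_values={})
        feats = pd.DataFrame({"x": np.zeros(n)})
        surv = simulate_survival(feats, hz,
                                 CensoringSpec(horizon_days=1e9,
                                               random_rate_per_day=0.0),
                                 seed=21)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(surv["survival_days"], surv["event"])
        ts = np.linspace(50, 8000, 200)
        km_s = km.survival_function_at_times(ts).to_numpy()
        wb_s = np.exp(-((ts / hz.baseline_scale_days) ** hz.baseline_shape))
        assert np.abs(km_s - wb_s).max() < 0.05
        assert (surv["event"] == 1).all()

    def test_cox_recovers_driver_coefficient(self):
        from lifelines import CoxPHFitter

        df = generate_feature_cohort(2000, 42, hazard=recovery_hazard())
        d = pd.DataFrame({"x": df["LA_mean_eqd2"], "age": df["age"],
                          "sexM": df["sex_M"], "psq": df["pathology_squamous"],
                          "t": df["survival_days"], "e": df["event"]})
        cph = CoxPHFitter().fit(d, "t", "e")
        beta, se = cph.params_["x"], cph.standard_errors_["x"]
        assert abs(beta - math.log(1.05)) < 2 * se

    def test_zero_horizon_censors_everyone(self):
        feats = pd.DataFrame({"x": np.ones(10)})
        hz = HazardSpec(log_hazard_coefficients={"x": 0.1}, driver_feature="x",
                        reference_values={})
        surv = simulate_survival(feats, hz, CensoringSpec(horizon_days=0.0),
                                 seed=1)
        assert (surv["event"] == 0).all()
        assert (surv["survival_days"] == 0).all()

    def test_missing_feature_names_patient(self):
        feats = pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"])
        hz = HazardSpec(log_hazard_coefficients={"x": 0.1}, driver_feature="x")
        with pytest.raises(DataError, match="b"):
            simulate_survival(feats, hz, CensoringSpec(), seed=0)


class TestFeatureCohort:
    def test_variant_monotonicity(self):
        _, variants = generate_feature_cohort(80, 5, return_variants=True)
        orig = variants[("original", "standard")]
        exp = variants[("expanded", "standard")]
        con = variants[("contracted", "standard")]
        max_cols = [c for c in orig.columns if c.endswith("_max_eqd2")]
        assert (exp[max_cols].to_numpy() >= orig[max_cols].to_numpy() - 1e-12).all()
        assert (orig[max_cols].to_numpy() >= con[max_cols].to_numpy() - 1e-12).all()

    def test_max_at_least_mean(self):
        df = generate_feature_cohort(200, 3)
        for s in ("LA", "LV", "SVC", "RL"):
            assert (df[f"{s}_max_eqd2"] >= df[f"{s}_mean_eqd2"] - 1e-12).all()

    def test_deterministic(self):
        a = generate_feature_cohort(40, 17)
        b = generate_feature_cohort(40, 17)
        pd.testing.assert_frame_equal(a, b)
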