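"""Unit tests for the blood-chemistry aging algorithms."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from socmob import bioage
from socmob.bioage import (
    HDParams, KDMParams, age_adjust, load_phenoage_coefficients,
    phenoage_from_risk, risk_at_age, score_hd, score_kdm, score_phenoage,
    train_hd, train_kdm,
)


def _linear_reference(n=200, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    age = np.linspace(20, 80, n)
    return pd.DataFrame({
        "age": age,
        "m1": 10 + 0.5 * age + noise * rng.standard_normal(n),
        "m2": 40 - 0.2 * age + noise * rng.standard_normal(n),
    })


class TestKDM:
    def test_exact_linear_data_recovers_coefficients(self):
        params = train_kdm(_linear_reference(), ["m1", "m2"], s_ba2=5.0)
        assert params.q[0] == pytest.approx(10.0, abs=1e-6)
        assert params.k[0] == pytest.approx(0.5, abs=1e-6)
        assert params.q[1] == pytest.approx(40.0, abs=1e-6)

    def test_recovers_generator_ground_truth(self, reference, config):
        params = train_kdm(reference)
        by_name = {(f"{s.name}_log" if s.log_scale else s.name): s
                   for s in config.biomarker_specs}
        for name, q, k in zip(params.biomarkers, params.q, params.k):
            spec = by_name[name]
            assert k == pytest.approx(spec.age_slope, rel=0.02)
            assert q == pytest.approx(spec.intercept, rel=0.02)

    def test_flat_biomarker_rejected(self):
        ref = _linear_reference()
        ref["flat"] = 3.0
        with pytest.raises(ValueError, match="flat"):
            train_kdm(ref, ["m1", "flat"])

    def test_identity_calibration(self):
        # one biomarker with q=0, k=1, s=1 and a vanishing CA channel:
        # the score is just the biomarker value
        params = KDMParams(("m",), np.array([0.0]), np.array([1.0]),
                           np.array([1.0]), s_ba2=1e12)
        panel = pd.DataFrame({"m": [50.0], "age": [30.0]})
        assert score_kdm(panel, params) == pytest.approx(50.0, abs=1e-6)

    def test_subject_on_regression_line_scores_chronological_age(self, reference):
        params = train_kdm(reference)
        age = np.array([35.0, 62.5])
        panel = pd.DataFrame({"age": age})
        for name, q, k in zip(params.biomarkers, params.q, params.k):
            panel[name] = q + k * age
        assert np.allclose(score_kdm(panel, params), age, atol=1e-8)

    def test_closed_form_equals_weighted_ssq_minimizer(self):
        # independent oracle: 1-D numeric minimization of the weighted SSQ
        rng = np.random.default_rng(4)
        m = 5
        params = KDMParams(tuple(f"b{i}" for i in range(m)),
                           q=rng.normal(50, 10, m), k=rng.uniform(0.2, 1.0, m),
                           s=rng.uniform(0.5, 2.0, m), s_ba2=rng.uniform(5, 50))
        for _ in range(20):
            x = params.q + params.k * rng.uniform(20, 90) + rng.normal(0, params.s)
            ca = rng.uniform(20, 90)
            panel = pd.DataFrame([dict(zip(params.biomarkers, x), age=ca)])

            def ssq(ba):
                return (np.sum(((x - params.q - params.k * ba) / params.s) ** 2)
                        + (ca - ba) ** 2 / params.s_ba2)

            oracle = minimize_scalar(ssq, bounds=(-200, 400), method="bounded",
                                     options={"xatol": 1e-10}).x
            assert score_kdm(panel, params)[0] == pytest.approx(oracle, abs=1e-6)

    def test_missing_biomarker_scores_missing(self, reference):
        params = train_kdm(reference)
        panel = pd.DataFrame({name: [50.0] for name in params.biomarkers})
        panel["age"] = 60.0
        panel.loc[0, params.biomarkers[0]] = np.nan
        assert np.isnan(score_kdm(panel, params)[0])


class TestHD:
    def _uncorrelated_reference(self, n=2000, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.uniform(20, 30, n),
            "obese": np.zeros(n, dtype=int),
            "m1": rng.standard_normal(n),
            "m2": rng.standard_normal(n),
        })

    def test_uncorrelated_markers_give_identity_covariance(self):
        params = train_hd(self._uncorrelated_reference(), ["m1", "m2"])
        assert np.allclose(params.cov, np.eye(2), atol=0.1)

    def test_filter_excludes_old_and_obese(self):
        ref = self._uncorrelated_reference()
        junk = ref.copy()
        junk["age"] = 55.0
        junk[["m1", "m2"]] += 100.0  # would wreck the covariance if included
        params = train_hd(pd.concat([ref, junk], ignore_index=True), ["m1", "m2"])
        assert np.allclose(params.cov, np.eye(2), atol=0.1)
        assert abs(params.center).max() < 0.2

    def test_reference_mean_scores_log_epsilon(self):
        params = train_hd(self._uncorrelated_reference(), ["m1", "m2"])
        panel = pd.DataFrame({"m1": [params.center[0]], "m2": [params.center[1]]})
        assert score_hd(panel, params) == pytest.approx(np.log(bioage.HD_LOG_EPS))

    def test_unit_displacement_identity_cov_gives_zero(self):
        params = HDParams(("m1", "m2"), center=np.zeros(2), scale=np.ones(2),
                          cov=np.eye(2))
        panel = pd.DataFrame({"m1": [1.0], "m2": [0.0]})
        assert score_hd(panel, params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_quadratic_form(self, reference):
        params = train_hd(reference)
        panel = reference.sample(50, random_state=0)
        got = score_hd(panel, params)
        z = (bioage.prepare_biomarkers(panel)[list(params.biomarkers)].to_numpy()
             - params.center) / params.scale
        inv = np.linalg.inv(params.cov)
        expect = np.log(np.einsum("ij,jk,ik->i", z, inv, z))
        assert np.allclose(got, expect, atol=1e-10)

    def test_scale_equivariance(self, reference):
        # rescaling a biomarker consistently in reference and panel is a no-op
        scaled = reference.copy()
        scaled["albumin"] = scaled["albumin"] * 7.3
        panel = reference.sample(30, random_state=1)
        panel_scaled = panel.copy()
        panel_scaled["albumin"] = panel_scaled["albumin"] * 7.3
        a = score_hd(panel, train_hd(reference))
        b = score_hd(panel_scaled, train_hd(scaled))
        assert np.allclose(a, b, atol=1e-10)

    def test_too_small_subset_raises(self):
        ref = self._uncorrelated_reference(n=2)
        with pytest.raises(ValueError, match="young-healthy"):
            train_hd(ref, ["m1", "m2"])


class TestPhenoAge:
    def test_round_trip_identity(self):
        coeffs = load_phenoage_coefficients()
        ages = np.linspace(20, 100, 401)
        back = phenoage_from_risk(risk_at_age(ages, coeffs), coeffs)
        assert np.allclose(back, ages, atol=1e-8)

    def test_monotone_in_positive_weight_biomarker(self, reference):
        coeffs = load_phenoage_coefficients()
        row = bioage.prepare_biomarkers(reference).iloc[[0, 0]].copy()
        row = row.reset_index(drop=True)
        row.loc[1, "glucose"] += 2.0  # positive weight
        lo, hi = score_phenoage(row, coeffs)
        assert hi > lo

    def test_subject_at_reference_norm_scores_own_age(self, reference):
        # build a subject whose computed mortality risk equals the reference
        # norm at age a; the algorithm must return a
        coeffs = load_phenoage_coefficients()
        a = 70.0
        target_risk = risk_at_age(a, coeffs)
        # solve for the glucose value producing that risk, other markers fixed
        row = bioage.prepare_biomarkers(reference).iloc[[0]].copy()
        row["age"] = 55.0
        lp_needed = np.log(-np.log1p(-target_risk)
                           / (np.expm1(coeffs.gamma * coeffs.horizon_months)
                              / coeffs.gamma))
        lp_other = coeffs.intercept + coeffs.age_weight * 55.0
        for name, w in coeffs.weights.items():
            if name != "glucose":
                lp_other += w * row[name].iloc[0]
        row["glucose"] = (lp_needed - lp_other) / coeffs.weights["glucose"]
        assert score_phenoage(row, coeffs)[0] == pytest.approx(a, abs=1e-6)

    def test_biomarker_set_validated(self):
        coeffs = load_phenoage_coefficients()
        bad = dict(coeffs.weights)
        bad.pop("glucose")
        with pytest.raises(ValueError, match="glucose"):
            bioage.PhenoAgeCoefficients(
                weights=bad, age_weight=coeffs.age_weight,
                intercept=coeffs.intercept, gamma=coeffs.gamma,
                horizon_months=120, calib_age_anchor=141.5,
                calib_risk_scale=0.00553, calib_age_rate=0.09)


class TestAgeAdjust:
    def test_difference_and_passthrough(self):
        age = np.array([60.0, 70.0])
        measures = pd.DataFrame({
            "phenoage_blood": [65.0, 68.0],
            "kdm_ba": age,                      # exactly on age: adv = 0
            "hd": [1.2, 3.4],
            "dunedin_poam": [1.1, 0.9],
        })
        adv = age_adjust(measures, age)
        assert np.allclose(adv["kdm_adv"], 0.0)
        assert np.allclose(adv["phenoage_blood_adv"], [5.0, -2.0])
        assert np.allclose(adv["hd_adv"], measures["hd"])
        assert np.allclose(adv["dunedin_poam_adv"], [1.1, 0.9])

    def test_clock_residuals_orthogonal_to_age(self, cohort):
        subj = cohort.subjects
        adv = age_adjust(subj[["phenoage_clock", "grimage_clock"]],
                         subj["age_at_draw"])
        for col in ("phenoage_clock_adv", "grimage_clock_adv"):
            r = np.corrcoef(adv[col], subj["age_at_draw"])[0, 1]
            assert abs(r) < 1e-10


def test_advancement_measures_positively_track_latent_aging(analysis, cohort):
    # all three blood-chemistry advancement values are positive readouts of
    # the generator's latent aging variable, and correlate with each other
    lat = cohort.latent["latent_aging"]
    for col in ("phenoage_blood_adv", "kdm_adv", "hd_adv"):
        ok = analysis[col].notna()
        assert np.corrcoef(analysis[col][ok], lat[ok])[0, 1] > 0.3
    blood = analysis[["phenoage_blood_adv", "kdm_adv", "hd_adv"]].dropna()
    assert (np.corrcoef(blood.T) > 0.2).all()


def test_reference_model_json_round_trip(reference, tmp_path):
    model = bioage.train_reference_model(reference)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = bioage.ReferenceModel.from_json(path)
    assert np.allclose(loaded.kdm.q, model.kdm.q)
    assert np.allclose(loaded.hd.cov, model.hd.cov)
    panel = reference.sample(20, random_state=2)
    assert np.allclose(score_kdm(panel, loaded.kdm, age_col="age"),
                       score_kdm(panel, model.kdm, age_col="age"))
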