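"""Association models: standardized effects, cluster-robust errors,
interaction tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from socmob.models import (
    ModelSpec, cluster_robust_cov, fit_ba_model, fit_interaction_model,
    run_effect_table,
)
from socmob.synthetic import SyntheticConfig, generate_cohort


def test_planted_mobility_effect_recovered_roughly(analysis):
    est = fit_ba_model(analysis, ModelSpec(outcome="kdm_adv",
                                           exposure="resid_change_z"))
    assert est.beta == pytest.approx(-0.20, abs=0.06)
    assert est.ci_low < est.beta < est.ci_high
    assert est.n_clusters <= est.n


def test_permuted_exposure_is_null(analysis):
    rng = np.random.default_rng(0)
    d = analysis.dropna(subset=["resid_change_z", "kdm_adv"]).copy()
    d["resid_change_z"] = rng.permutation(d["resid_change_z"].to_numpy())
    est = fit_ba_model(d, ModelSpec(outcome="kdm_adv", exposure="resid_change_z"))
    assert abs(est.beta) < 3 * est.se


def test_outcome_rescaling_leaves_standardized_beta_unchanged(analysis):
    est1 = fit_ba_model(analysis, ModelSpec(outcome="kdm_adv",
                                            exposure="origins_z"))
    rescaled = analysis.copy()
    rescaled["kdm_adv"] = rescaled["kdm_adv"] * 2.0
    est2 = fit_ba_model(rescaled, ModelSpec(outcome="kdm_adv",
                                            exposure="origins_z"))
    assert est1.beta == pytest.approx(est2.beta, abs=1e-10)


def test_no_covariate_beta_is_pearson_r():
    rng = np.random.default_rng(5)
    n = 400
    x = rng.standard_normal(n)
    y = 0.3 * x + rng.standard_normal(n)
    d = pd.DataFrame({"y": y, "x": x, "household_id": np.arange(n),
                      "age_at_draw": rng.uniform(50, 90, n),
                      "sex": "female", "race": "White", "hispanic": 0})
    est = fit_ba_model(d, ModelSpec(outcome="y", exposure="x", covariates="1"))
    assert est.beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


class TestClusterRobustCov:
    def _fit(self, n=600, icc=0.0, seed=0, couple=True):
        rng = np.random.default_rng(seed)
        if couple:
            g = np.repeat(np.arange(n // 2), 2)
        else:
            g = np.arange(n)
        u = rng.standard_normal(g.max() + 1)[g]
        e = np.sqrt(icc) * u + np.sqrt(1 - icc) * rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = 0.2 * x + e
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        return X, y, resid, g

    def test_matches_statsmodels_cluster_estimator(self):
        X, y, resid, g = self._fit(icc=0.5)
        ours = cluster_robust_cov(X, resid, g)
        res = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": g, "use_correction": True})
        assert np.allclose(ours, res.cov_params(), rtol=1e-10)

    def test_singleton_clusters_equal_hc0(self):
        X, y, resid, g = self._fit(couple=False)
        ours = cluster_robust_cov(X, resid, g, correction="CR0")
        hc0 = sm.OLS(y, X).fit(cov_type="HC0").cov_params()
        assert np.allclose(ours, hc0, rtol=1e-10)

    def test_independent_errors_close_to_classical_se(self):
        X, y, resid, g = self._fit(n=500, icc=0.0, couple=False, seed=3)
        cr_se = np.sqrt(cluster_robust_cov(X, resid, g)[1, 1])
        classical = np.sqrt(sm.OLS(y, X).fit().cov_params()[1, 1])
        assert abs(cr_se / classical - 1) < 0.10

    def test_within_cluster_correlation_inflates_se(self):
        # both x and errors shared within couples -> clustering must matter
        rng = np.random.default_rng(7)
        n = 2000
        g = np.repeat(np.arange(n // 2), 2)
        x = rng.standard_normal(n // 2)[g]
        e = (np.sqrt(0.8) * rng.standard_normal(n // 2)[g]
             + np.sqrt(0.2) * rng.standard_normal(n))
        y = 0.2 * x + e
        X = np.column_stack([np.ones(n), x])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        cr_se = np.sqrt(cluster_robust_cov(X, resid, g)[1, 1])
        classical = np.sqrt(sm.OLS(y, X).fit().cov_params()[1, 1])
        assert cr_se > 1.2 * classical

    def test_duplicating_rows_within_cluster_stable(self, analysis):
        spec = ModelSpec(outcome="kdm_adv", exposure="origins_z")
        base = fit_ba_model(analysis, spec)
        doubled = pd.concat([analysis, analysis], ignore_index=True)
        dup = fit_ba_model(doubled, spec)
        assert dup.beta == pytest.approx(base.beta, abs=1e-10)
        assert dup.se == pytest.approx(base.se, rel=0.05)

    def test_one_cluster_raises(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="one cluster"):
            cluster_robust_cov(X, np.ones(4), np.zeros(4))


class TestInteraction:
    def test_delta_equals_stratum_difference_no_covariates(self):
        # reparameterization identity on a saturated no-covariate model:
        # the interaction coefficient equals the difference between
        # per-stratum slopes fitted separately
        rng = np.random.default_rng(2)
        n = 600
        z = (rng.random(n) < 0.5).astype(float)
        x = rng.standard_normal(n)
        y = 0.2 * x - 0.15 * x * z + 0.3 * z + rng.standard_normal(n)
        ys = (y - y.mean()) / y.std()
        xs = (x - x.mean()) / x.std()
        d = pd.DataFrame({"y": ys, "x": xs, "z": z,
                          "household_id": np.arange(n),
                          "age_at_draw": 60.0, "sex": "female",
                          "race": "White", "hispanic": 0})
        est = fit_interaction_model(
            d, ModelSpec(outcome="y", exposure="x", covariates="1",
                         modifier="z", standardize_exposure=False))
        # independent per-stratum least squares on the same arrays
        slopes = []
        for val in (0.0, 1.0):
            m = z == val
            X = np.column_stack([np.ones(m.sum()), xs[m]])
            slopes.append(np.linalg.lstsq(X, ys[m], rcond=None)[0][1])
        assert est.beta == pytest.approx(slopes[1] - slopes[0], abs=1e-10)

    def test_planted_sex_interaction_recovered(self):
        cfg = SyntheticConfig(n_subjects=20_000, seed=17,
                              delta_mobility_sex=-0.10)
        coh = generate_cohort(cfg)
        d = coh.subjects[["household_id", "age_at_draw", "sex", "race",
                          "hispanic", "dunedin_poam"]].copy()
        d["mobility"] = coh.latent["mobility"].to_numpy()
        est = fit_interaction_model(
            d, ModelSpec(outcome="dunedin_poam", exposure="mobility",
                         modifier="sex"))
        true_delta = np.sqrt(cfg.poam_reliability) * -0.10
        assert est.beta == pytest.approx(true_delta, abs=0.03)

    def test_race_modifier_restricts_to_black_white(self, analysis):
        est = fit_interaction_model(
            analysis, ModelSpec(outcome="kdm_adv", exposure="resid_change_z",
                                modifier="race_bw"))
        n_bw = analysis.dropna(subset=["kdm_adv", "resid_change_z"])
        n_bw = (n_bw["race"].isin(["White", "Black"])).sum()
        assert est.n == n_bw

    def test_constant_modifier_raises(self, analysis):
        d = analysis.copy()
        d["mod"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_interaction_model(
                d, ModelSpec(outcome="kdm_adv", exposure="origins_z",
                             modifier="mod"))


def test_rank_deficient_design_names_aliased_terms(analysis):
    d = analysis.copy()
    d["copy_of_exposure"] = d["origins_z"]
    spec = ModelSpec(outcome="kdm_adv", exposure="origins_z",
                     extra_terms=("copy_of_exposure",))
    with pytest.raises(ValueError, match="aliased"):
        fit_ba_model(d, spec)


class TestEffectTable:
    @pytest.fixture(scope="class")
    def table(self, analysis):
        subgroups = {"women": analysis["sex"] == "female",
                     "men": analysis["sex"] == "male"}
        return run_effect_table(
            analysis, outcomes=("kdm_adv", "dunedin_poam_adv"),
            exposures={"origins": ("origins_z", True),
                       "resid_change": ("resid_change_z", True)},
            subgroups=subgroups)

    def test_row_count(self, table):
        assert len(table) == 2 * 2 * 3  # exposures x outcomes x (all, women, men)

    def test_cis_bracket_betas(self, table):
        assert ((table["ci_low"] <= table["beta"])
                & (table["beta"] <= table["ci_high"])).all()

    def test_subgroup_labels_carried(self, table):
        assert set(table["subgroup"]) == {"all", "women", "men"}
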