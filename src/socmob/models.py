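"""Standardized association models with household-clustered errors.

The core regression is ``BA = a + b*SES + g*X + e`` where ``BA`` is one of
six standardized biological-aging advancement measures, ``SES`` is a
standardized socioeconomic exposure (origins, attainment, a mobility metric,
or education terms reported per category step), and ``X`` is the covariate
set: chronological age as a centered quadratic, sex, race, Hispanic
ethnicity, and the interactions of both age terms with each demographic.
Standard errors are clustered at the household level (CR1 sandwich,
inference on a t reference with G-1 degrees of freedom, G = number of
households). With both sides standardized and no covariates, the coefficient
is exactly the Pearson correlation.

Effect modification is tested by adding a cross-product term
``SES x Z`` (plus the main effect of Z); the interaction coefficient delta
measures how the SES association differs across strata of Z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "EffectEstimate", "DEFAULT_COVARIATES",
    "fit_ba_model", "fit_interaction_model", "cluster_robust_cov",
    "run_effect_table",
]

# age terms are centered before squaring (reduces collinearity, leaves
# fitted values unchanged)
DEFAULT_COVARIATES = (
    "age_c + age_c2 + C(sex) + C(race) + hispanic"
    " + age_c:C(sex) + age_c:C(race) + age_c:hispanic"
    " + age_c2:C(sex) + age_c2:C(race) + age_c2:hispanic"
)
# covariates when the sample is restricted to Black/White subjects and race
# enters as the modifier
COVARIATES_NO_RACE = (
    "age_c + age_c2 + C(sex) + hispanic"
    " + age_c:C(sex) + age_c:hispanic + age_c2:C(sex) + age_c2:hispanic"
)


@dataclass
class ModelSpec:
    """One exposure x outcome model.

    ``standardize_exposure=False`` reports the effect per unit of the
    exposure (used for education indices, reported per category step).
    """

    outcome: str
    exposure: str
    covariates: str = DEFAULT_COVARIATES
    modifier: str | None = None
    cluster: str = "household_id"
    age_col: str = "age_at_draw"
    standardize_exposure: bool = True
    subgroup: str | None = None          # label carried into result rows
    extra_terms: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class EffectEstimate:
    term: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_clusters: int
    outcome: str = ""
    exposure: str = ""
    subgroup: str | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "outcome", "exposure", "subgroup", "term", "beta", "se",
            "ci_low", "ci_high", "p_value", "n", "n_clusters")}


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - np.nanmean(x)) / np.nanstd(x)


def _prepare(data: pd.DataFrame, spec: ModelSpec,
             extra_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = {spec.outcome, spec.exposure, spec.cluster, spec.age_col,
            "sex", "race", "hispanic", *extra_cols}
    d = data[[c for c in cols if c in data.columns]].copy()
    d = d.dropna()
    d["age_c"] = d[spec.age_col].astype(float) - d[spec.age_col].astype(float).mean()
    d["age_c2"] = d["age_c"] ** 2
    d["hispanic"] = d["hispanic"].astype(int)
    d["_y"] = _standardize(d[spec.outcome].to_numpy(float))
    x = d[spec.exposure].to_numpy(float)
    d["_x"] = _standardize(x) if spec.standardize_exposure else x
    return d


def _check_design(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, piv = scipy.linalg.qr(exog, pivoting=True, mode="economic")
        aliased = [model.exog_names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _fit_clustered(formula: str, d: pd.DataFrame, cluster: str):
    groups = pd.factorize(d[cluster])[0]
    n_clusters = int(groups.max()) + 1
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters for cluster-robust errors")
    sizes = np.bincount(groups)
    if sizes.max() == 1:
        warnings.warn("all clusters are singletons; cluster-robust errors "
                      "reduce to heteroskedasticity-robust", stacklevel=3)
    model = smf.ols(formula, data=d)
    _check_design(model)
    res = model.fit(cov_type="cluster",
                    cov_kwds={"groups": groups, "use_correction": True,
                              "df_correction": True},
                    use_t=True)
    return res, n_clusters


def _extract(res, term: str, n: int, n_clusters: int,
             spec: ModelSpec) -> EffectEstimate:
    beta = float(res.params[term])
    se = float(res.bse[term])
    ci = res.conf_int().loc[term]
    return EffectEstimate(
        term=term, beta=beta, se=se,
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(res.pvalues[term]), n=n, n_clusters=n_clusters,
        outcome=spec.outcome, exposure=spec.exposure, subgroup=spec.subgroup)


def fit_ba_model(data: pd.DataFrame, spec: ModelSpec) -> EffectEstimate:
    """Standardized association of one SES exposure with one aging outcome,
    with the full covariate set and household-clustered errors."""
    d = _prepare(data, spec,
                 extra_cols=tuple(t for t in spec.extra_terms
                                  if t in data.columns))
    rhs = " + ".join(["_x", spec.covariates, *spec.extra_terms])
    res, n_clusters = _fit_clustered(f"_y ~ {rhs}", d, spec.cluster)
    return _extract(res, "_x", len(d), n_clusters, spec)


def fit_interaction_model(data: pd.DataFrame, spec: ModelSpec) -> EffectEstimate:
    """Effect-modification test: delta on the SES x Z cross-product.

    ``modifier`` may be "sex" (female indicator), "race_bw" (Black
    indicator; the sample is restricted to Black and White subjects and the
    race covariate is dropped), or any numeric column (e.g. the origins
    z-score for modification across the origins distribution). The main
    effect of Z is always included.
    """
    if spec.modifier is None:
        raise ValueError("spec.modifier is required for an interaction model")
    covariates = spec.covariates
    interaction = "_x*_z"
    if spec.modifier == "sex":
        d = _prepare(data, spec)
        d["_z"] = (d["sex"] == "female").astype(float)
        # the main effect of sex is already in the covariate set
        interaction = "_x + _x:_z"
    elif spec.modifier == "race_bw":
        d = _prepare(data, spec)
        d = d[d["race"].isin(["White", "Black"])].copy()
        d["_z"] = (d["race"] == "Black").astype(float)
        covariates = COVARIATES_NO_RACE
    else:
        d = _prepare(data, spec, extra_cols=(spec.modifier,))
        d["_z"] = d[spec.modifier].astype(float)
    if d["_z"].nunique() < 2:
        raise ValueError(f"modifier {spec.modifier!r} is constant in the sample")
    rhs = " + ".join([interaction, covariates, *spec.extra_terms])
    res, n_clusters = _fit_clustered(f"_y ~ {rhs}", d, spec.cluster)
    return _extract(res, "_x:_z", len(d), n_clusters, spec)


def cluster_robust_cov(
    design: np.ndarray,
    residuals: np.ndarray,
    cluster_ids: np.ndarray,
    correction: str = "CR1",
) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of OLS coefficients.

    Meat: sum over clusters of the outer products of cluster-summed scores
    ``X_g' u_g``. ``correction="CR1"`` applies the finite-sample factor
    ``G/(G-1) * (n-1)/(n-k)``; ``"CR0"`` applies none. With all-singleton
    clusters CR0 equals the HC0 heteroskedasticity-robust estimator.
    """
    X = np.asarray(design, float)
    u = np.asarray(residuals, float)
    codes, uniques = pd.factorize(np.asarray(cluster_ids))
    n_clusters = len(uniques)
    if n_clusters < 2:
        raise ValueError("cluster-robust variance undefined with one cluster")
    n, k = X.shape
    scores = np.zeros((n_clusters, k))
    np.add.at(scores, codes, X * u[:, None])
    meat = scores.T @ scores
    bread = np.linalg.inv(X.T @ X)
    if correction == "CR1":
        c = n_clusters / (n_clusters - 1) * (n - 1) / (n - k)
    elif correction == "CR0":
        c = 1.0
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return c * bread @ meat @ bread


# default exposure set mirroring the main-text analysis: column name and
# whether the effect is reported per SD (True) or per category step (False)
DEFAULT_EXPOSURES = {
    "origins": ("origins_z", True),
    "attainment": ("attainment_z", True),
    "resid_change": ("resid_change_z", True),
    "diff_score": ("diff_score_z", True),
    "edu_mobility": ("edu_mobility", False),
}


def run_effect_table(
    data: pd.DataFrame,
    outcomes: tuple[str, ...],
    exposures: dict[str, tuple[str, bool]] = DEFAULT_EXPOSURES,
    subgroups: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """One standardized effect estimate per exposure x outcome (x subgroup)
    cell, as a long machine-readable table."""
    rows = []
    cells = [("all", None)] + list((subgroups or {}).items())
    for label, mask in cells:
        sub = data if mask is None else data[mask.reindex(data.index, fill_value=False)]
        for exp_name, (col, std) in exposures.items():
            if col not in data.columns:
                log.warning("exposure column %s missing; skipped", col)
                continue
            for outcome in outcomes:
                if outcome not in data.columns:
                    log.warning("outcome column %s missing; skipped", outcome)
                    continue
                spec = ModelSpec(outcome=outcome, exposure=col,
                                 standardize_exposure=std, subgroup=label)
                est = fit_ba_model(sub, spec)
                est.exposure = exp_name
                rows.append(est.to_dict())
    return pd.DataFrame(rows)
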