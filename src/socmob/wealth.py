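"""Later-life socioeconomic attainment from multi-wave household wealth.

Nominal net worth reported across survey waves is (1) inflated to constant
2012 dollars with a consumer-price-index table, (2) averaged across a
subject's observed waves (both members of a couple carry the household
value), (3) passed through the inverse hyperbolic sine to tame skew while
remaining defined for zero and negative net worth, and (4) given a "theta"
normalization: residualized on age (quadratic) and sex, then mapped through
a rank-based inverse-normal transform (Blom offset) so the attainment score
is approximately standard normal. Z-scores and percentile ranks of the
result form the attainment score.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "load_cpi", "default_cpi_table", "inflate_to_constant_dollars",
    "ihs_transform", "household_wealth_resolution", "theta_transform",
    "attainment_scores", "build_attainment_index",
]

BASE_YEAR = 2012


def packaged_cpi_path() -> Path:
    return Path(resources.files("socmob").joinpath("data/cpi_synthetic.csv"))


def load_cpi(path: str | Path) -> pd.Series:
    """Read a (year, index) price-index table into a Series keyed by year."""
    table = pd.read_csv(path, comment="#")
    return pd.Series(table["index"].to_numpy(float),
                     index=table["year"].astype(int).to_numpy(), name="cpi")


def default_cpi_table() -> pd.Series:
    return load_cpi(packaged_cpi_path())


def inflate_to_constant_dollars(amount, year, cpi: pd.Series,
                                base_year: int = BASE_YEAR):
    """``amount * index[base_year] / index[year]``; debts stay negative.

    Only index ratios matter, so rescaling the whole table is a no-op.
    """
    scalar = np.isscalar(amount) and np.isscalar(year)
    amount = np.atleast_1d(np.asarray(amount, float))
    year = np.atleast_1d(np.asarray(year, int))
    missing = sorted(set(np.unique(year)) - set(cpi.index)
                     | ({base_year} - set(cpi.index)))
    if missing:
        raise ValueError(f"price-index table missing year(s): {missing}")
    out = amount * (cpi[base_year] / cpi.loc[year].to_numpy())
    return float(out[0]) if scalar else out


def ihs_transform(x):
    """Inverse hyperbolic sine, ``ln(x + sqrt(x^2 + 1))``: odd, defined at 0,
    ~ln(2x) for large x."""
    return np.arcsinh(np.asarray(x, float))


def household_wealth_resolution(
    wealth: pd.DataFrame,
    cpi: pd.Series | None = None,
    base_year: int = BASE_YEAR,
) -> pd.Series:
    """Per-subject constant-dollar net worth: the mean across observed waves
    of wave net worth inflated to the base year. Expects long format
    (subject_id, year, net_worth_nominal); subjects with zero waves are
    simply absent from the result."""
    if cpi is None:
        cpi = default_cpi_table()
    constant = inflate_to_constant_dollars(
        wealth["net_worth_nominal"], wealth["year"], cpi, base_year)
    return (pd.Series(constant, index=wealth["subject_id"].to_numpy())
            .groupby(level=0).mean().rename("constant_dollar_wealth"))


def theta_transform(
    ihs_wealth: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    method: str = "rint",
) -> pd.Series:
    """Age/sex-adjusted normalization of IHS wealth.

    Default ("rint"): apply the rank-based inverse-normal transform with the
    Blom offset, then residualize on a quadratic in age plus sex by least
    squares and rescale to unit variance. Normalizing before adjusting makes
    the output exactly uncorrelated with the age terms (IHS wealth can be
    strongly bimodal around zero net worth, in which case adjusting first
    and rank-transforming afterwards re-introduces age dependence through
    the nonlinear rank map). The result is approximately standard normal and
    monotone in wealth within (age, sex) strata. A Yeo-Johnson power-fit
    alternative is available via ``method="yeojohnson"``.
    """
    ihs_wealth = pd.Series(np.asarray(ihs_wealth, float),
                           index=pd.Series(ihs_wealth).index)
    ok = ihs_wealth.notna() & pd.Series(age).notna() & pd.Series(sex).notna()
    v = ihs_wealth[ok].to_numpy()
    if len(v) < 2 or np.allclose(v, v[0]):
        raise ValueError("theta transform degenerate: wealth values all identical")
    if method == "rint":
        n = len(v)
        ranks = stats.rankdata(v, method="average")
        normalized = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    elif method == "yeojohnson":
        shifted, _ = stats.yeojohnson(v - v.min())
        normalized = (shifted - shifted.mean()) / shifted.std(ddof=0)
    else:
        raise ValueError(f"unknown theta method {method!r}")
    a = np.asarray(age, float)[np.asarray(ok)]
    a = a - a.mean()
    female = (np.asarray(sex, object)[np.asarray(ok)] == "female").astype(float)
    X = np.column_stack([np.ones_like(a), a, a ** 2, female])
    beta, *_ = np.linalg.lstsq(X, normalized, rcond=None)
    resid = normalized - X @ beta
    theta = resid / resid.std(ddof=0)
    sw = stats.shapiro(theta[:5000]) if len(theta) >= 3 else None
    if sw is not None:
        log.info("theta normality diagnostic (Shapiro W on first 5000): %.4f", sw[0])
    out = pd.Series(np.nan, index=ihs_wealth.index)
    out[ok] = theta
    return out.rename("theta_value")


def attainment_scores(theta: pd.Series) -> pd.DataFrame:
    """Z-scores and overall percentile ranks of the theta values.

    Ranks are over the whole sample (not within birth cohorts); average
    ranks for ties.
    """
    theta = pd.Series(theta)
    ok = theta.notna()
    if ok.sum() < 2:
        raise ValueError("need at least 2 nonmissing attainment values")
    v = theta[ok].to_numpy()
    z = pd.Series(np.nan, index=theta.index)
    z[ok] = (v - v.mean()) / v.std(ddof=0)
    pct = pd.Series(np.nan, index=theta.index)
    pct[ok] = 100.0 * stats.rankdata(v, method="average") / len(v)
    return pd.DataFrame({"z_score": z, "percentile_rank": pct})


def build_attainment_index(
    subjects: pd.DataFrame,
    wealth: pd.DataFrame,
    cpi: pd.Series | None = None,
    base_year: int = BASE_YEAR,
    theta_method: str = "rint",
) -> pd.DataFrame:
    """Full attainment chain, indexed like ``subjects``."""
    resolved = household_wealth_resolution(wealth, cpi, base_year)
    const = subjects["subject_id"].map(resolved)
    const.index = subjects.index
    ihs = ihs_transform(const)
    theta = theta_transform(pd.Series(ihs, index=subjects.index),
                            subjects["age_at_draw"], subjects["sex"],
                            method=theta_method)
    scores = attainment_scores(theta)
    return pd.DataFrame({
        "constant_dollar_wealth": const,
        "ihs_wealth": ihs,
        "theta_value": theta,
        "z_score": scores["z_score"],
        "percentile_rank": scores["percentile_rank"],
    })
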