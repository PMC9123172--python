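"""Childhood social origins index.

Four retrospective childhood items -- family financial circumstances,
father's occupation score, economic hardship (pre-coded so higher values
mean less hardship), and parents' education -- are combined into a single
index:

1. the first principal component is fit on complete cases (loadings from the
   4x4 correlation matrix, sign fixed so higher = more advantaged);
2. missing father's-occupation and parents'-education values are imputed at
   the means of cells defined by race x 5-year birth cohort x a band of the
   family-finances score, with logged fallback to coarser cells;
3. factor scores are the mean of loading-weighted standardized items over
   the available items, computed for subjects with at least 3 of the 4 items
   (mean rather than sum keeps 3- and 4-item scores on the same scale);
4. scores are converted to z-scores and to percentile ranks within 5-year
   birth cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import CHILDHOOD_ITEMS

log = logging.getLogger(__name__)

__all__ = [
    "OriginsModel", "fit_origins_pca", "impute_missing_items",
    "score_origins", "percentile_rank_within_cohort", "build_origins_index",
]

IMPUTABLE_ITEMS = ("chd_father_occupation", "chd_parent_education")
SIGN_ANCHOR_ITEM = "chd_parent_education"


@dataclass
class OriginsModel:
    """First-principal-component loadings and the complete-case
    standardization used when scoring."""

    items: tuple[str, ...]
    loadings: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_complete: int
    explained_share: float


def fit_origins_pca(
    table: pd.DataFrame,
    items: tuple[str, ...] = CHILDHOOD_ITEMS,
    min_complete: int = 50,
    sign_anchor: str = SIGN_ANCHOR_ITEM,
) -> OriginsModel:
    """First principal component of the items' correlation matrix, fit on
    complete cases, sign fixed so the loading on parents' education is
    positive (higher index = more advantaged family of origin)."""
    complete = table[list(items)].dropna()
    if len(complete) < min_complete:
        raise ValueError(
            f"only {len(complete)} complete cases on all {len(items)} items; "
            f"need at least {min_complete}")
    means = complete.mean().to_numpy()
    sds = complete.std(ddof=1).to_numpy()
    zero = [it for it, s in zip(items, sds) if s == 0 or not np.isfinite(s)]
    if zero:
        raise ValueError(f"degenerate (zero-variance) item(s): {zero}")
    corr = np.corrcoef((complete.to_numpy() - means) / sds, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    anchor = list(items).index(sign_anchor)
    flip = loadings[anchor] if abs(loadings[anchor]) > 1e-12 else loadings.sum()
    if flip < 0:
        loadings = -loadings
    return OriginsModel(tuple(items), loadings, means, sds,
                        n_complete=len(complete),
                        explained_share=float(eigvals[-1] / eigvals.sum()))


def _cohort_bin(birth_year: pd.Series, width: int = 5, anchor: int = 1900) -> pd.Series:
    return anchor + width * np.floor((birth_year - anchor) / width)


def impute_missing_items(
    table: pd.DataFrame,
    items: tuple[str, ...] = IMPUTABLE_ITEMS,
    race_col: str = "race",
    birth_year_col: str = "birth_year",
    finances_col: str = "chd_family_finances",
    n_finance_bands: int = 5,
    cohort_width: int = 5,
    cohort_anchor: int = 1900,
) -> pd.DataFrame:
    """Group-mean imputation of father's occupation and parents' education.

    Cells are race x 5-year birth cohort x finances-score band (quintiles of
    the observed finances score). Cells with no observed donors fall back to
    progressively coarser cells (drop the finances band, then the cohort,
    then race), ending at the grand mean; the fallback level is recorded per
    imputed value and logged. Only these two items are ever imputed.
    """
    out = table.copy()
    cohort = _cohort_bin(out[birth_year_col], cohort_width, cohort_anchor)
    fin = out[finances_col]
    try:
        band = pd.qcut(fin, n_finance_bands, labels=False, duplicates="drop")
    except ValueError:
        band = pd.Series(0, index=out.index)
    levels = [
        [out[race_col], cohort, band],
        [out[race_col], cohort],
        [out[race_col]],
    ]
    for item in items:
        vals = out[item]
        missing = vals.isna()
        out[f"{item}_imputed"] = missing
        fallback = pd.Series(np.where(missing, -1, 0), index=out.index)
        filled = vals.copy()
        for lvl, keys in enumerate(levels):
            cell_mean = vals.groupby(keys, dropna=False).transform("mean")
            use = filled.isna() & cell_mean.notna()
            filled[use] = cell_mean[use]
            fallback[use] = lvl
        still = filled.isna()
        if still.any():
            filled[still] = vals.mean()
            fallback[still] = len(levels)
        out[item] = filled
        out[f"{item}_fallback_level"] = fallback
        n_fb = int(((fallback > 0) & missing).sum())
        if n_fb:
            log.info("imputation for %s: %d of %d imputed values used a "
                     "coarser fallback cell", item, n_fb, int(missing.sum()))
    return out


def score_origins(
    table: pd.DataFrame,
    model: OriginsModel,
    min_items: int = 3,
) -> pd.DataFrame:
    """Factor scores: mean over available items of loading x standardized
    item; subjects with fewer than ``min_items`` available items are missing.
    Returns factor_score, its in-sample z-score, and n_items_used."""
    z = (table[list(model.items)].to_numpy(float) - model.means) / model.sds
    weighted = z * model.loadings
    n_items = np.isfinite(weighted).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        factor = np.nanmean(weighted, axis=1)
    factor[n_items < min_items] = np.nan
    ok = np.isfinite(factor)
    zscore = np.full_like(factor, np.nan)
    if ok.sum() > 1:
        zscore[ok] = (factor[ok] - factor[ok].mean()) / factor[ok].std(ddof=0)
    return pd.DataFrame({
        "factor_score": factor,
        "z_score": zscore,
        "n_items_used": n_items,
    }, index=table.index)


def percentile_rank_within_cohort(
    values: pd.Series,
    birth_year: pd.Series,
    width: int = 5,
    anchor: int = 1900,
) -> pd.Series:
    """Percentile ranks in (0, 100] among members of the same 5-year birth
    cohort, with average ranks for ties; missing values are excluded."""
    values = pd.Series(values)
    cohort = _cohort_bin(pd.Series(birth_year, index=values.index), width, anchor)
    out = pd.Series(np.nan, index=values.index)
    for _, idx in values.groupby(cohort, dropna=False).groups.items():
        v = values.loc[idx].dropna()
        if v.empty:
            continue
        if len(v) == 1:
            warnings.warn("birth cohort of size 1; percentile rank set to 100",
                          stacklevel=2)
        out.loc[v.index] = 100.0 * rankdata(v.to_numpy(), method="average") / len(v)
    return out


def build_origins_index(
    table: pd.DataFrame,
    cohort_width: int = 5,
    cohort_anchor: int = 1900,
    min_complete: int = 50,
) -> pd.DataFrame:
    """Full origins pipeline: fit PCA on complete cases, impute, score,
    z-score, and percentile-rank within birth cohorts."""
    model = fit_origins_pca(table, min_complete=min_complete)
    imputed = impute_missing_items(
        table, cohort_width=cohort_width, cohort_anchor=cohort_anchor)
    scores = score_origins(imputed, model)
    scores["percentile_rank"] = percentile_rank_within_cohort(
        scores["factor_score"], table["birth_year"],
        width=cohort_width, anchor=cohort_anchor)
    for item in IMPUTABLE_ITEMS:
        scores[f"{item}_imputed"] = imputed[f"{item}_imputed"]
    return scores
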