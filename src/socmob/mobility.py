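"""Social-mobility metrics and the educational-mobility index.

Two complementary mobility metrics, each on two scales:

* **Residualized change** -- the residual from a least-squares regression of
  the attainment score on the origins score: mobility net of what origins
  predict. Exactly orthogonal to origins in-sample.
* **Difference score** -- attainment minus origins: the absolute change in
  standing.

Both are computed from z-scores and (in parallel) from percentile ranks, and
are z-scored for effect-size reporting.

Educational mobility compares the participant's credential category
(1 = less than high school, 2 = high-school graduate without a college
degree, 3 = college degree or more) with the parental category (low/average/
high, cut at the 25th and 75th percentiles of parents' years of schooling
within the participant's 5-year birth cohort, taking the higher-attainment
parent). The index is the participant category minus the parental category,
an integer in [-2, 2]; positive values are upward mobility.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .origins import percentile_rank_within_cohort

__all__ = [
    "residualized_change", "difference_score", "percentile_mobility",
    "years_to_credential", "code_participant_education",
    "code_parent_education", "educational_mobility", "build_mobility_table",
]


def _zscore(values: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    ok = np.isfinite(values)
    sd = values[ok].std(ddof=0)
    out[ok] = (values[ok] - values[ok].mean()) / sd
    return out


def residualized_change(origins, attainment) -> pd.DataFrame:
    """Residuals of attainment regressed on origins (raw and z-scored)."""
    origins = pd.Series(origins).astype(float)
    attainment = pd.Series(attainment, index=origins.index).astype(float)
    ok = origins.notna() & attainment.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired nonmissing values")
    o = origins[ok].to_numpy()
    a = attainment[ok].to_numpy()
    if o.std(ddof=0) == 0:
        raise ValueError("origins score has zero variance")
    slope, intercept = np.polyfit(o, a, 1)
    raw = np.full(len(origins), np.nan)
    raw[np.asarray(ok)] = a - (intercept + slope * o)
    return pd.DataFrame({"raw": raw, "z": _zscore(raw)}, index=origins.index)


def difference_score(origins, attainment) -> pd.DataFrame:
    """Attainment minus origins (raw and z-scored)."""
    origins = pd.Series(origins).astype(float)
    attainment = pd.Series(attainment, index=origins.index).astype(float)
    raw = (attainment - origins).to_numpy()
    return pd.DataFrame({"raw": raw, "z": _zscore(raw)}, index=origins.index)


def percentile_mobility(origins_pct, attainment_pct) -> pd.DataFrame:
    """Both mobility metrics computed on the percentile-rank scale."""
    rc = residualized_change(origins_pct, attainment_pct)
    ds = difference_score(origins_pct, attainment_pct)
    return pd.DataFrame({
        "resid_change_pct_raw": rc["raw"], "resid_change_pct_z": rc["z"],
        "diff_score_pct_raw": ds["raw"], "diff_score_pct_z": ds["z"],
    })


_CREDENTIAL_IDX = {"less_than_hs": 1, "hs": 2, "college": 3}


def years_to_credential(years) -> pd.Series:
    """Map years of schooling to a credential: >=16 college degree, >=12
    high-school graduate, otherwise less than high school."""
    years = pd.Series(years).astype(float)
    out = pd.Series(pd.NA, index=years.index, dtype=object)
    out[years < 12] = "less_than_hs"
    out[years >= 12] = "hs"
    out[years >= 16] = "college"
    return out


def code_participant_education(credential=None, years=None) -> pd.Series:
    """Participant education index: 1 = less than high school, 2 =
    high-school graduate without a college degree, 3 = college degree+."""
    if credential is None:
        if years is None:
            raise ValueError("provide credential or years")
        credential = years_to_credential(years)
    credential = pd.Series(credential)
    unknown = sorted(set(credential.dropna()) - set(_CREDENTIAL_IDX))
    if unknown:
        raise ValueError(f"unknown credential code(s): {unknown}")
    return credential.map(_CREDENTIAL_IDX).astype("Int64")


def code_parent_education(
    parent_years: pd.DataFrame | pd.Series,
    birth_year: pd.Series,
    cohort_width: int = 5,
    cohort_anchor: int = 1900,
) -> pd.Series:
    """Parental education index from years of schooling.

    Each parent's years are percentile-ranked within the participant's
    5-year birth cohort; categories cut below the 25th (low = 1), in the
    closed interval [25th, 75th] (average = 2), and above the 75th
    (high = 3). The participant gets the highest category of either parent;
    missing if both parents are missing.
    """
    if isinstance(parent_years, pd.Series):
        parent_years = parent_years.to_frame()
    cats = []
    for col in parent_years.columns:
        years = parent_years[col]
        if years.dropna().nunique() <= 1 and years.notna().sum() > 1:
            warnings.warn(
                f"parental education column {col!r} has a single value; all "
                "subjects coded average", stacklevel=2)
        pct = percentile_rank_within_cohort(
            years, birth_year, width=cohort_width, anchor=cohort_anchor)
        cat = pd.Series(np.nan, index=years.index)
        cat[pct < 25] = 1
        cat[(pct >= 25) & (pct <= 75)] = 2
        cat[pct > 75] = 3
        cats.append(cat)
    combined = pd.concat(cats, axis=1).max(axis=1)
    return combined.astype("Int64")


def educational_mobility(participant_idx, parent_idx) -> pd.Series:
    """Participant index minus parental index, an integer in [-2, 2];
    positive values are upward educational mobility."""
    participant_idx = pd.Series(participant_idx).astype("Int64")
    parent_idx = pd.Series(parent_idx, index=participant_idx.index).astype("Int64")
    for name, v in (("participant", participant_idx), ("parent", parent_idx)):
        bad = sorted(set(v.dropna().unique()) - {1, 2, 3})
        if bad:
            raise ValueError(f"{name} education index out of range: {bad}")
    return participant_idx - parent_idx


def build_mobility_table(
    origins_scores: pd.DataFrame,
    attainment_scores: pd.DataFrame,
    subjects: pd.DataFrame,
    cohort_width: int = 5,
    cohort_anchor: int = 1900,
) -> pd.DataFrame:
    """All mobility measures for a cohort, joined on the subject index."""
    rc = residualized_change(origins_scores["z_score"], attainment_scores["z_score"])
    ds = difference_score(origins_scores["z_score"], attainment_scores["z_score"])
    pct = percentile_mobility(origins_scores["percentile_rank"],
                              attainment_scores["percentile_rank"])
    p_idx = code_participant_education(years=subjects["education_years"])
    parent_cols = [c for c in ("father_education_years", "mother_education_years")
                   if c in subjects.columns]
    par_idx = code_parent_education(
        subjects[parent_cols], subjects["birth_year"],
        cohort_width=cohort_width, cohort_anchor=cohort_anchor)
    out = pd.DataFrame({
        "resid_change_raw": rc["raw"], "resid_change_z": rc["z"],
        "diff_score_raw": ds["raw"], "diff_score_z": ds["z"],
        "participant_edu_idx": p_idx, "parent_edu_idx": par_idx,
        "edu_mobility": educational_mobility(p_idx, par_idx),
    }, index=subjects.index)
    return pd.concat([out, pct], axis=1)
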