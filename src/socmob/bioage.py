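"""Blood-chemistry biological-aging algorithms and age adjustment.

Three published algorithm families are implemented:

* **KDM Biological Age** (Klemera-Doubal): the age at which a subject's
  biomarker profile best matches reference-population age norms. Each
  biomarker is regressed on chronological age in the reference panel; the
  score is the precision-weighted combination of the per-biomarker age
  predictions plus a chronological-age channel.
* **Homeostatic dysregulation**: log squared Mahalanobis distance of the
  biomarker vector from a young, healthy reference subsample (nonobese,
  ages 20-30), with biomarkers standardized to that subsample.
* **PhenoAge**: a Gompertz mortality model on a linear biomarker predictor,
  inverted through the reference risk-vs-age calibration to an age in years.
  Coefficients ship as a versioned text file transcribed from the published
  source; they are inputs, not constants invented here.

``age_adjust`` produces the "advancement" forms used as regression outcomes:
PhenoAge and KDM Biological Age are differenced from chronological age; DNAm
clocks are residualized on chronological age; homeostatic dysregulation and
DunedinPoAm pass through unchanged (the former is not on an age scale, the
latter is already a rate).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SHARED_BIOMARKERS", "PHENOAGE_BIOMARKERS", "KDM_HD_BIOMARKERS",
    "KDMParams", "HDParams", "PhenoAgeCoefficients", "ReferenceModel",
    "prepare_biomarkers", "train_kdm", "score_kdm", "train_hd", "score_hd",
    "load_phenoage_coefficients", "score_phenoage",
    "phenoage_from_risk", "risk_at_age",
    "age_adjust", "ADVANCEMENT_COLUMNS",
]

# Eight chemistries shared by all three algorithms; PhenoAge adds glucose,
# KDM Biological Age and homeostatic dysregulation add glycated hemoglobin.
SHARED_BIOMARKERS = (
    "albumin", "alkaline_phosphatase", "creatinine", "crp_log",
    "wbc", "lymphocyte_pct", "mcv", "rdw",
)
PHENOAGE_BIOMARKERS = SHARED_BIOMARKERS + ("glucose",)
KDM_HD_BIOMARKERS = SHARED_BIOMARKERS + ("hba1c",)

ADVANCEMENT_COLUMNS = (
    "phenoage_blood_adv", "kdm_adv", "hd_adv",
    "phenoage_clock_adv", "grimage_clock_adv", "dunedin_poam_adv",
)

CRP_FLOOR = 1e-3  # mg/dL floor before taking the log


def prepare_biomarkers(panel: pd.DataFrame, crp_col: str = "crp") -> pd.DataFrame:
    """Add the log-scale C-reactive protein column used by all algorithms.

    Nonpositive CRP values are floored at ``CRP_FLOOR`` mg/dL before the log.
    """
    out = panel.copy()
    if crp_col in out.columns and "crp_log" not in out.columns:
        out["crp_log"] = np.log(np.clip(out[crp_col].astype(float), CRP_FLOOR, None))
    return out


# --------------------------------------------------------------------------
# KDM Biological Age
# --------------------------------------------------------------------------

@dataclass
class KDMParams:
    """Per-biomarker age regressions (intercept q, slope k, residual SD s)
    plus the variance of the chronological-age channel, s_BA2."""

    biomarkers: tuple[str, ...]
    q: np.ndarray
    k: np.ndarray
    s: np.ndarray
    s_ba2: float

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "q": self.q.tolist(), "k": self.k.tolist(), "s": self.s.tolist(),
            "s_ba2": self.s_ba2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KDMParams":
        return cls(tuple(d["biomarkers"]), np.asarray(d["q"], float),
                   np.asarray(d["k"], float), np.asarray(d["s"], float),
                   float(d["s_ba2"]))


def train_kdm(
    reference: pd.DataFrame,
    biomarkers: Sequence[str] = KDM_HD_BIOMARKERS,
    age_col: str = "age",
    s_ba2: float | None = None,
    slope_tol: float = 1e-8,
    s_ba2_floor: float = 1e-3,
) -> KDMParams:
    """Fit the per-biomarker age regressions and the s_BA2 variance term.

    s_BA2 follows the Klemera-Doubal estimate
    ``mean((BA_E - CA)^2) - ((1 - rchar^2)/rchar^2) * range(CA)^2 / (12 m)``
    with ``rchar`` the characteristic correlation coefficient, floored at a
    small positive value; an explicit override is accepted.
    """
    reference = prepare_biomarkers(reference)
    q, k, s, r = [], [], [], []
    age = reference[age_col].to_numpy(float)
    for name in biomarkers:
        sub = reference[[age_col, name]].dropna()
        if len(sub) < 30:
            raise ValueError(f"reference has fewer than 30 rows for biomarker {name!r}")
        a = sub[age_col].to_numpy(float)
        x = sub[name].to_numpy(float)
        slope, intercept = np.polyfit(a, x, 1)
        if abs(slope) < slope_tol:
            raise ValueError(
                f"biomarker {name!r} rejected: age slope {slope:.3g} below tolerance "
                f"{slope_tol} (slope enters the score as a divisor)")
        resid = x - (intercept + slope * a)
        q.append(intercept)
        k.append(slope)
        s.append(float(np.std(resid, ddof=2)))
        r.append(abs(np.corrcoef(a, x)[0, 1]))
    q, k, s, r = map(np.asarray, (q, k, s, r))
    params = KDMParams(tuple(biomarkers), q, k, s, s_ba2=1.0)

    if s_ba2 is None:
        ba_e = score_kdm(reference, params, age_col=age_col, include_ca=False)
        ok = np.isfinite(ba_e) & np.isfinite(age)
        mse = float(np.mean((ba_e[ok] - age[ok]) ** 2))
        with np.errstate(divide="ignore"):
            wr = r / np.sqrt(1.0 - r ** 2)
        rchar = float(np.sum(r * wr) / np.sum(wr))
        m = len(biomarkers)
        age_range = float(age[ok].max() - age[ok].min())
        correction = (1.0 - rchar ** 2) / rchar ** 2 * age_range ** 2 / (12.0 * m)
        s_ba2 = mse - correction
        if s_ba2 < s_ba2_floor:
            log.info("KDM s_BA2 estimate %.4g below floor; using %.4g",
                     s_ba2, s_ba2_floor)
            s_ba2 = s_ba2_floor
    params.s_ba2 = float(s_ba2)
    return params


def score_kdm(
    panel: pd.DataFrame,
    params: KDMParams,
    age_col: str = "age",
    include_ca: bool = True,
) -> np.ndarray:
    """Closed-form KDM Biological Age.

    ``BA = [sum_j (x_j - q_j) k_j / s_j^2 + CA/s_BA2] / [sum_j (k_j/s_j)^2 + 1/s_BA2]``,
    the minimizer of the weighted sum of squares over candidate ages. With
    ``include_ca=False`` the chronological-age channel is omitted (the BA_E
    variant). Subjects with any missing biomarker score as missing.
    """
    panel = prepare_biomarkers(panel)
    X = panel[list(params.biomarkers)].to_numpy(float)
    num = ((X - params.q) * (params.k / params.s ** 2)).sum(axis=1)
    den = float(((params.k / params.s) ** 2).sum())
    if include_ca:
        ca = panel[age_col].to_numpy(float)
        num = num + ca / params.s_ba2
        den = den + 1.0 / params.s_ba2
    return num / den


# --------------------------------------------------------------------------
# Homeostatic dysregulation
# --------------------------------------------------------------------------

HD_LOG_EPS = 1e-12  # floor on the squared distance before the log


@dataclass
class HDParams:
    """Young-healthy reference: per-biomarker standardization scales and the
    covariance of the standardized biomarkers."""

    biomarkers: tuple[str, ...]
    center: np.ndarray       # young-healthy means, original units
    scale: np.ndarray        # young-healthy SDs, original units
    cov: np.ndarray          # covariance of standardized biomarkers
    regularized: bool = False
    cov_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.cov_inv = np.linalg.inv(self.cov)

    def to_dict(self) -> dict:
        return {
            "biomarkers": list(self.biomarkers),
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "cov": self.cov.tolist(), "regularized": self.regularized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HDParams":
        return cls(tuple(d["biomarkers"]), np.asarray(d["center"], float),
                   np.asarray(d["scale"], float), np.asarray(d["cov"], float),
                   bool(d.get("regularized", False)))


def train_hd(
    reference: pd.DataFrame,
    biomarkers: Sequence[str] = KDM_HD_BIOMARKERS,
    age_col: str = "age",
    obese_col: str = "obese",
    max_condition: float = 1e12,
) -> HDParams:
    """Mean/covariance of the young, healthy subsample (nonobese, age 20-30)."""
    reference = prepare_biomarkers(reference)
    young = reference[
        (reference[obese_col] == 0)
        & reference[age_col].between(20, 30)
    ][list(biomarkers)].dropna()
    p = len(biomarkers)
    if len(young) <= p:
        raise ValueError(
            f"young-healthy subset has {len(young)} rows; need more than the "
            f"{p} biomarkers for an invertible covariance")
    center = young.mean().to_numpy()
    scale = young.std(ddof=1).to_numpy()
    if np.any(scale == 0):
        bad = [b for b, s in zip(biomarkers, scale) if s == 0]
        raise ValueError(f"zero variance in young-healthy subset for {bad}")
    z = (young.to_numpy() - center) / scale
    cov = np.cov(z, rowvar=False)
    regularized = False
    if np.linalg.cond(cov) > max_condition:
        log.warning("HD covariance ill-conditioned; adding 1e-8 ridge")
        cov = cov + 1e-8 * np.eye(p)
        regularized = True
    return HDParams(tuple(biomarkers), center, scale, cov, regularized)


def score_hd(panel: pd.DataFrame, params: HDParams) -> np.ndarray:
    """Log squared Mahalanobis distance from the young-healthy reference.

    The squared distance is floored at ``HD_LOG_EPS`` before the log so the
    measure is defined at the reference mean. Missing biomarkers yield a
    missing score.
    """
    panel = prepare_biomarkers(panel)
    z = (panel[list(params.biomarkers)].to_numpy(float) - params.center) / params.scale
    d2 = np.einsum("ij,jk,ik->i", z, params.cov_inv, z)
    return np.log(np.clip(d2, HD_LOG_EPS, None))


# --------------------------------------------------------------------------
# PhenoAge
# --------------------------------------------------------------------------

@dataclass
class PhenoAgeCoefficients:
    weights: dict[str, float]        # per-biomarker linear-predictor weights
    age_weight: float
    intercept: float
    gamma: float                     # Gompertz shape, per month
    horizon_months: float
    calib_age_anchor: float
    calib_risk_scale: float
    calib_age_rate: float
    source: str = ""

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("Gompertz shape parameter must be > 0")
        expected = set(PHENOAGE_BIOMARKERS)
        got = set(self.weights)
        if got != expected:
            raise ValueError(
                f"PhenoAge biomarker set mismatch: missing {sorted(expected - got)}, "
                f"unexpected {sorted(got - expected)}")


def packaged_phenoage_path() -> Path:
    return Path(resources.files("socmob").joinpath("data/phenoage_levine2018.csv"))


def load_phenoage_coefficients(path: str | Path | None = None) -> PhenoAgeCoefficients:
    """Read the (biomarker, weight) coefficient file with its metadata header."""
    path = Path(path) if path is not None else packaged_phenoage_path()
    table = pd.read_csv(path, comment="#")
    vals = dict(zip(table["term"], table["value"].astype(float)))
    consts = {}
    for key in ("intercept", "age", "gompertz_gamma", "horizon_months",
                "calib_age_anchor", "calib_risk_scale", "calib_age_rate"):
        if key not in vals:
            raise ValueError(f"coefficient file {path} missing term {key!r}")
        consts[key] = vals.pop(key)
    return PhenoAgeCoefficients(
        weights=vals,
        age_weight=consts["age"],
        intercept=consts["intercept"],
        gamma=consts["gompertz_gamma"],
        horizon_months=consts["horizon_months"],
        calib_age_anchor=consts["calib_age_anchor"],
        calib_risk_scale=consts["calib_risk_scale"],
        calib_age_rate=consts["calib_age_rate"],
        source=str(path),
    )


_RISK_EPS = 1e-15


def risk_at_age(age, coeffs: PhenoAgeCoefficients):
    """Reference-norm 10-year mortality risk at a given (Pheno)age.

    This is the inverse of :func:`phenoage_from_risk`: the risk a subject
    must carry for the algorithm to assign them this age.
    """
    age = np.asarray(age, float)
    z = np.exp(coeffs.calib_age_rate * (age - coeffs.calib_age_anchor))
    return 1.0 - np.exp(-z / coeffs.calib_risk_scale)


def phenoage_from_risk(risk, coeffs: PhenoAgeCoefficients):
    """Map 10-year mortality risk to the reference age scale."""
    risk = np.asarray(risk, float)
    return (coeffs.calib_age_anchor
            + np.log(-coeffs.calib_risk_scale * np.log1p(-risk))
            / coeffs.calib_age_rate)


def score_phenoage(
    panel: pd.DataFrame,
    coeffs: PhenoAgeCoefficients,
    age_col: str = "age",
) -> np.ndarray:
    """Blood-chemistry PhenoAge: linear predictor -> Gompertz 10-year
    mortality risk -> age at which that risk matches the reference norm.

    Monotone increasing in the linear predictor. Boundary risks (0 or 1) are
    clamped with a warning; missing biomarkers yield missing output.
    """
    panel = prepare_biomarkers(panel)
    lp = np.full(len(panel), coeffs.intercept, float)
    for name, w in coeffs.weights.items():
        lp = lp + w * panel[name].to_numpy(float)
    lp = lp + coeffs.age_weight * panel[age_col].to_numpy(float)
    scale = np.expm1(coeffs.gamma * coeffs.horizon_months) / coeffs.gamma
    risk = -np.expm1(-np.exp(lp) * scale)
    if np.any((risk <= 0) | (risk >= 1)):
        warnings.warn("PhenoAge mortality risk at boundary; clamping", stacklevel=2)
        risk = np.clip(risk, _RISK_EPS, 1.0 - _RISK_EPS)
    return phenoage_from_risk(risk, coeffs)


# --------------------------------------------------------------------------
# Serialized reference model & age adjustment
# --------------------------------------------------------------------------

@dataclass
class ReferenceModel:
    """Trained parameters for the three blood-chemistry aging algorithms."""

    kdm: KDMParams
    hd: HDParams
    phenoage_source: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {"kdm": self.kdm.to_dict(), "hd": self.hd.to_dict(),
                   "phenoage_source": self.phenoage_source}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        d = json.loads(Path(path).read_text())
        return cls(KDMParams.from_dict(d["kdm"]), HDParams.from_dict(d["hd"]),
                   d.get("phenoage_source", ""))


def train_reference_model(reference: pd.DataFrame) -> ReferenceModel:
    coeffs = load_phenoage_coefficients()
    return ReferenceModel(kdm=train_kdm(reference), hd=train_hd(reference),
                          phenoage_source=coeffs.source)


def score_all(panel: pd.DataFrame, model: ReferenceModel,
              age_col: str = "age_at_draw") -> pd.DataFrame:
    """Score the three blood-chemistry measures on a cohort panel."""
    coeffs = load_phenoage_coefficients()
    panel = prepare_biomarkers(panel)
    return pd.DataFrame({
        "phenoage_blood": score_phenoage(panel, coeffs, age_col=age_col),
        "kdm_ba": score_kdm(panel, model.kdm, age_col=age_col),
        "hd": score_hd(panel, model.hd),
    }, index=panel.index)


def _residualize_on_age(values: np.ndarray, age: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    ok = np.isfinite(values) & np.isfinite(age)
    if ok.sum() < 3:
        return out
    slope, intercept = np.polyfit(age[ok], values[ok], 1)
    out[ok] = values[ok] - (intercept + slope * age[ok])
    return out


def age_adjust(measures: pd.DataFrame, age: pd.Series | np.ndarray) -> pd.DataFrame:
    """Advancement forms of the six aging measures.

    PhenoAge and KDM Biological Age are differenced from chronological age;
    the DNAm PhenoAge and GrimAge clocks are residualized on chronological
    age in-sample; homeostatic dysregulation (not on an age scale) and
    DunedinPoAm (already a rate) pass through unchanged.
    """
    age = np.asarray(age, float)
    out = pd.DataFrame(index=measures.index)
    if "phenoage_blood" in measures:
        out["phenoage_blood_adv"] = measures["phenoage_blood"].to_numpy(float) - age
    if "kdm_ba" in measures:
        out["kdm_adv"] = measures["kdm_ba"].to_numpy(float) - age
    if "hd" in measures:
        out["hd_adv"] = measures["hd"].to_numpy(float)
    for clock in ("phenoage_clock", "grimage_clock"):
        if clock in measures:
            out[f"{clock}_adv"] = _residualize_on_age(
                measures[clock].to_numpy(float), age)
    if "dunedin_poam" in measures:
        out["dunedin_poam_adv"] = measures["dunedin_poam"].to_numpy(float)
    return out
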