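"""Synthetic cohort and reference-panel generation.

This module emulates the data structures of a large US aging cohort with a
venous blood draw (an HRS/VBS-like table: demographics, retrospective
childhood socioeconomic items, multi-wave household wealth, a blood-chemistry
panel, and precomputed DNA-methylation aging values) together with an
NHANES-like reference panel used to parameterize the blood-chemistry
biological-aging algorithms.

The generative model is latent-variable based so that every downstream stage
has known ground truth:

* ``O ~ N(0,1)`` is latent childhood social origins.
* ``M ~ N(0,1)`` is the mobility shock, independent of ``O``.
* ``A = rho*O + sqrt(1-rho^2)*M`` is latent later-life attainment, so
  ``corr(O, A) = rho`` and ``M`` is (up to scale) the residual of ``A`` on
  ``O`` -- exactly what the residualized-change mobility metric estimates.
* Latent aging
  ``L = beta_origins*O + beta_attainment*A + beta_mobility*M + u_h + e``,
  scaled to unit variance, where ``u_h`` is a household random effect shared
  by couples. The planted marginal standardized effect of the mobility shock
  is therefore ``beta_mobility + beta_attainment*sqrt(1-rho^2)``.
* Blood chemistries follow ``x_j = q_j + k_j*(age + c*L) + N(0, s_j)`` so
  that age-regression-based aging algorithms recover ``L``; DNAm aging values
  are affine transforms of ``L`` plus independent noise, with DunedinPoAm
  centered at 1 (the benchmark pace of one year of physiological decline per
  calendar year in midlife adults).
* Childhood items load on ``O``; multi-wave nominal wealth is a monotone
  (sinh) function of household attainment inflated to nominal dollars.

Couples share a household id, a household random effect, and household
wealth; their attainment is correlated (default 0.8) via shared components of
``O`` (assortative mating) and ``M``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "BiomarkerSpec",
    "SyntheticConfig",
    "SyntheticCohort",
    "DEFAULT_BIOMARKER_SPECS",
    "generate_cohort",
    "generate_reference_panel",
    "simulate_drm_data",
    "planted_marginal_effects",
    "household_sigma_for_outcome_corr",
]

SURVEY_YEAR = 2016
WAVE_YEARS = tuple(range(1994, 2017, 2))


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Linear age model for one blood chemistry: x = intercept + slope*age + N(0, sd).

    ``log_scale`` means the linear model lives on the log scale and the
    emitted column is the exponential (used for C-reactive protein, which the
    aging algorithms consume as log CRP).
    """

    name: str
    intercept: float
    age_slope: float
    resid_sd: float
    log_scale: bool = False


# Signal-rich defaults: slope/residual-SD ratios are set high so the aging
# algorithms are near-noiseless readouts of the latent L (see docs/methods.md).
DEFAULT_BIOMARKER_SPECS: tuple[BiomarkerSpec, ...] = (
    BiomarkerSpec("albumin", 47.0, -0.08, 0.40),          # g/L
    BiomarkerSpec("alkaline_phosphatase", 60.0, 0.50, 2.50),  # U/L
    BiomarkerSpec("creatinine", 70.0, 0.30, 1.50),        # umol/L
    BiomarkerSpec("crp", -1.50, 0.010, 0.050, log_scale=True),  # mg/dL, log scale
    BiomarkerSpec("wbc", 5.50, 0.020, 0.100),             # 10^9 cells/L
    BiomarkerSpec("lymphocyte_pct", 35.0, -0.12, 0.60),   # %
    BiomarkerSpec("mcv", 88.0, 0.070, 0.350),             # fL
    BiomarkerSpec("rdw", 12.5, 0.020, 0.100),             # %
    BiomarkerSpec("glucose", 4.80, 0.015, 0.075),         # mmol/L
    BiomarkerSpec("hba1c", 5.20, 0.012, 0.060),           # %
)

CHILDHOOD_ITEMS = (
    "chd_family_finances",
    "chd_father_occupation",
    "chd_hardship",
    "chd_parent_education",
)

DEFAULT_MISSING_RATES = {
    "chd_family_finances": 0.03,
    "chd_father_occupation": 0.10,
    "chd_hardship": 0.03,
    "chd_parent_education": 0.06,
}


@dataclass
class SyntheticConfig:
    """Ground-truth configuration of the synthetic cohort.

    Effect sizes are standardized (SD of the latent aging outcome per SD of
    the latent exposure). ``beta_attainment`` is the direct attainment effect
    beyond what flows through origins and the mobility shock; the marginal
    planted mobility effect is ``beta_mobility + beta_attainment*sqrt(1-rho^2)``
    (see :func:`planted_marginal_effects`).
    """

    n_subjects: int = 10_000
    couple_fraction: float = 0.5
    seed: int = 1
    age_range: tuple[float, float] = (50.0, 90.0)
    beta_origins: float = -0.05
    beta_attainment: float = 0.0
    beta_mobility: float = -0.20
    rho_origins_attainment: float = 0.5
    # interaction (effect-modification) switches, 0 = no planted interaction
    delta_mobility_sex: float = 0.0      # extra mobility effect for women
    delta_mobility_black: float = 0.0    # extra mobility effect for Black subjects
    biomarker_specs: tuple[BiomarkerSpec, ...] = DEFAULT_BIOMARKER_SPECS
    household_sigma: float = 0.30        # SD of shared household effect on L
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    # latent-to-measurement mapping
    aging_scale_years: float = 8.0       # years of biological age per SD of L
    clock_sd_years: float = 4.0          # SD of DNAm clock deviation, years
    clock_reliability: float = 0.96      # share of clock-deviation variance from L
    poam_sd: float = 0.10                # SD of DunedinPoAm around 1
    poam_reliability: float = 0.96
    item_loading: float = 0.95           # childhood-item loading on O
    couple_attainment_corr: float = 0.8  # within-couple corr of latent A
    couple_origin_share: float = 0.4     # within-couple shared variance of O
    wealth_scale: float = 25_000.0       # dollars; net worth = scale*sinh(curve*latent+offset)
    wealth_curve: float = 1.0
    wealth_offset: float = 1.5
    wealth_noise_sd: float = 0.05        # household noise on the wealth latent
    race_probs: tuple[float, float, float] = (0.70, 0.18, 0.12)  # White, Black, other
    hispanic_prob: float = 0.10
    reference_age_range: tuple[float, float] = (18.0, 80.0)
    obesity_prob: float = 0.30

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        for name in ("couple_fraction", "clock_reliability", "poam_reliability",
                     "hispanic_prob", "obesity_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        rho = self.rho_origins_attainment
        if not -1.0 < rho < 1.0:
            raise ConfigError(f"rho_origins_attainment must be in (-1, 1), got {rho}")
        if not self.biomarker_specs:
            raise ConfigError("biomarker_specs must be nonempty")
        for spec in self.biomarker_specs:
            if spec.resid_sd <= 0:
                raise ConfigError(
                    f"biomarker_specs: residual SD must be > 0 for {spec.name!r}")
        if self.household_sigma < 0:
            raise ConfigError("household_sigma must be >= 0")
        if not 0.0 < self.item_loading < 1.0:
            raise ConfigError("item_loading must be in (0, 1)")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missing_rates[{name!r}] must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range must satisfy lo < hi")
        sm = self._couple_mobility_share()
        if not 0.0 <= sm <= 1.0:
            raise ConfigError(
                "couple_attainment_corr incompatible with couple_origin_share and "
                f"rho (implied shared mobility variance {sm:.3f} outside [0, 1])")
        if self._resid_var() <= 0:
            raise ConfigError(
                "effect sizes and household_sigma leave no residual variance for "
                "the latent aging outcome (sum of squares >= 1)")

    # -- derived quantities ----------------------------------------------
    def _a_origins(self) -> float:
        return self.beta_origins + self.beta_attainment * self.rho_origins_attainment

    def _a_mobility(self) -> float:
        s = np.sqrt(1.0 - self.rho_origins_attainment ** 2)
        return self.beta_mobility + self.beta_attainment * s

    def _mobility_coef_second_moment(self) -> float:
        # E[(a_M + d_s*F + d_b*B)^2] with F, B independent Bernoulli
        a = self._a_mobility()
        d, g = self.delta_mobility_sex, self.delta_mobility_black
        p_f, p_b = 0.5, self.race_probs[1]
        return (a * a + 2 * a * (d * p_f + g * p_b)
                + d * d * p_f + g * g * p_b + 2 * d * g * p_f * p_b)

    def _resid_var(self) -> float:
        return (1.0 - self._a_origins() ** 2 - self._mobility_coef_second_moment()
                - self.household_sigma ** 2)

    def _couple_mobility_share(self) -> float:
        rho2 = self.rho_origins_attainment ** 2
        return (self.couple_attainment_corr - rho2 * self.couple_origin_share) / (1.0 - rho2)


def planted_marginal_effects(config: SyntheticConfig) -> dict:
    """Analytic marginal standardized effects of each exposure on the latent L.

    These are the population regression coefficients of the unit-variance
    latent aging outcome on each standardized latent exposure taken alone
    (with no planted interactions).
    """
    rho = config.rho_origins_attainment
    s = np.sqrt(1.0 - rho ** 2)
    a_o, a_m = config._a_origins(), config._a_mobility()
    return {
        "origins": a_o,
        "mobility": a_m,
        "attainment": rho * a_o + s * a_m,
    }


def household_sigma_for_outcome_corr(
    target: float, config: SyntheticConfig, outcome_reliability: float = 1.0
) -> float:
    """Household-effect SD giving a target within-couple correlation of an
    outcome that reads L with the given reliability (share of variance)."""
    shared = (config._a_origins() ** 2 * config.couple_origin_share
              + config._a_mobility() ** 2 * config._couple_mobility_share())
    need = target / outcome_reliability - shared
    if need <= 0:
        raise ConfigError(
            f"target within-couple correlation {target} already exceeded by "
            "shared origin/mobility components")
    return float(np.sqrt(need))


@dataclass
class SyntheticCohort:
    """Generated cohort: subject table, long-format wealth table, and the
    latent ground truth (for tests and calibration checks only)."""

    subjects: pd.DataFrame
    wealth: pd.DataFrame
    latent: pd.DataFrame
    config: SyntheticConfig

    def to_csv_bytes(self) -> bytes:
        """Canonical byte serialization of the subject+wealth tables
        (used by determinism checks)."""
        buf = io.StringIO()
        self.subjects.to_csv(buf, index=False)
        self.wealth.to_csv(buf, index=False)
        return buf.getvalue().encode()


def _shared_factor(rng: np.random.Generator, hh_index: np.ndarray,
                   n_households: int, share: float) -> np.ndarray:
    """N(0,1) variable with variance `share` shared within household."""
    common = rng.standard_normal(n_households)[hh_index]
    own = rng.standard_normal(hh_index.shape[0])
    return np.sqrt(share) * common + np.sqrt(1.0 - share) * own


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a synthetic cohort table, deterministic given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    # households: couples first, then singles
    n_couples = int(n * config.couple_fraction) // 2
    n_coupled = 2 * n_couples
    n_households = n_couples + (n - n_coupled)
    hh_index = np.empty(n, dtype=np.int64)
    hh_index[:n_coupled] = np.repeat(np.arange(n_couples), 2)
    hh_index[n_coupled:] = np.arange(n_couples, n_households)

    # latent structure
    origins = _shared_factor(rng, hh_index, n_households, config.couple_origin_share)
    mobility = _shared_factor(rng, hh_index, n_households, config._couple_mobility_share())
    rho = config.rho_origins_attainment
    attainment = rho * origins + np.sqrt(1.0 - rho ** 2) * mobility

    # demographics
    sex = np.empty(n, dtype=object)
    sex[:n_coupled:2] = "female"
    sex[1:n_coupled:2] = "male"
    sex[n_coupled:] = np.where(rng.random(n - n_coupled) < 0.5, "female", "male")
    race = rng.choice(np.array(["White", "Black", "other"], dtype=object),
                      size=n, p=config.race_probs)
    hispanic = (rng.random(n) < config.hispanic_prob).astype(int)
    lo, hi = config.age_range
    age = np.round(rng.uniform(lo, hi, size=n), 1)
    birth_year = SURVEY_YEAR - np.floor(age).astype(int)

    # latent aging outcome, unit variance by construction
    female = (sex == "female").astype(float)
    black = (race == "Black").astype(float)
    m_coef = (config._a_mobility() + config.delta_mobility_sex * female
              + config.delta_mobility_black * black)
    u_house = config.household_sigma * rng.standard_normal(n_households)[hh_index]
    resid_sd = np.sqrt(config._resid_var())
    latent_aging = (config._a_origins() * origins + m_coef * mobility
                    + u_house + resid_sd * rng.standard_normal(n))

    # blood chemistries: x = q + k*(age + c*L) + noise
    ba_star = age + config.aging_scale_years * latent_aging
    biomarkers = {}
    for spec in config.biomarker_specs:
        vals = (spec.intercept + spec.age_slope * ba_star
                + spec.resid_sd * rng.standard_normal(n))
        biomarkers[spec.name] = np.exp(vals) if spec.log_scale else vals

    # DNAm aging values: affine readouts of L
    def _readout(scale: float, reliability: float) -> np.ndarray:
        noise = rng.standard_normal(n)
        return scale * (np.sqrt(reliability) * latent_aging
                        + np.sqrt(1.0 - reliability) * noise)

    phenoage_clock = age + _readout(config.clock_sd_years, config.clock_reliability)
    grimage_clock = age + _readout(config.clock_sd_years, config.clock_reliability)
    dunedin_poam = 1.0 + _readout(config.poam_sd, config.poam_reliability)

    # childhood socioeconomic items (load on O; hardship pre-coded so higher
    # values mean *less* hardship)
    lam = config.item_loading
    res = np.sqrt(1.0 - lam ** 2)

    def _item() -> np.ndarray:
        return lam * origins + res * rng.standard_normal(n)

    family_finances = 3.0 + _item()                 # 1-5-like relative standing
    father_occupation = 50.0 + 15.0 * _item()       # prestige-like score
    hardship = _item()                              # z-scale, higher = less hardship
    father_edu_years = np.clip(np.round(11.0 + 3.0 * _item()), 0, 17)
    mother_edu_years = np.clip(np.round(11.0 + 2.8 * _item()), 0, 17)
    parent_education = (father_edu_years + mother_edu_years) / 2.0

    # participant education: driven by origins and the mobility shock
    edu_latent = (0.55 * origins + 0.40 * mobility
                  + np.sqrt(1.0 - 0.55 ** 2 - 0.40 ** 2) * rng.standard_normal(n))
    education_years = np.clip(np.round(13.5 + 2.5 * edu_latent), 6, 20).astype(int)

    # item missingness (completely at random)
    items = {
        "chd_family_finances": family_finances,
        "chd_father_occupation": father_occupation,
        "chd_hardship": hardship,
        "chd_parent_education": parent_education,
    }
    for name, vals in items.items():
        rate = config.missing_rates.get(name, 0.0)
        if rate > 0:
            mask = rng.random(n) < rate
            vals = vals.astype(float).copy()
            vals[mask] = np.nan
            items[name] = vals

    subject_id = np.arange(1, n + 1)
    household_id = hh_index + 1

    subjects = pd.DataFrame({
        "subject_id": subject_id,
        "household_id": household_id,
        "birth_year": birth_year,
        "age_at_draw": age,
        "sex": sex,
        "race": race,
        "hispanic": hispanic,
        **items,
        "father_education_years": father_edu_years,
        "mother_education_years": mother_edu_years,
        "education_years": education_years,
        **{k: np.asarray(v) for k, v in biomarkers.items()},
        "phenoage_clock": phenoage_clock,
        "grimage_clock": grimage_clock,
        "dunedin_poam": dunedin_poam,
    })

    wealth = _generate_wealth(rng, config, subjects, attainment, hh_index, n_households)

    latent = pd.DataFrame({
        "subject_id": subject_id,
        "household_id": household_id,
        "origins": origins,
        "mobility": mobility,
        "attainment": attainment,
        "latent_aging": latent_aging,
    })
    return SyntheticCohort(subjects=subjects, wealth=wealth, latent=latent,
                           config=config)


def _generate_wealth(rng, config, subjects, attainment, hh_index, n_households):
    """Household-level multi-wave nominal net worth, monotone in household
    attainment; both members of a couple share the household rows."""
    from .wealth import default_cpi_table  # local import to avoid cycles

    cpi = default_cpi_table()
    base = cpi[2012]

    # household attainment = mean of members' latent A
    hh_sum = np.zeros(n_households)
    hh_cnt = np.zeros(n_households)
    np.add.at(hh_sum, hh_index, attainment)
    np.add.at(hh_cnt, hh_index, 1.0)
    hh_attain = hh_sum / hh_cnt
    w_latent = hh_attain + config.wealth_noise_sd * rng.standard_normal(n_households)
    wealth_2012 = config.wealth_scale * np.sinh(
        config.wealth_curve * w_latent + config.wealth_offset)

    n_waves = rng.integers(2, 6, size=n_households)
    rows_sid, rows_hid, rows_year, rows_amt = [], [], [], []
    wave_years = np.array(WAVE_YEARS)
    hh_waves = [np.sort(rng.choice(wave_years, size=k, replace=False))
                for k in n_waves]
    sid = subjects["subject_id"].to_numpy()
    hid = subjects["household_id"].to_numpy()
    for i in range(len(sid)):
        years = hh_waves[hh_index[i]]
        w12 = wealth_2012[hh_index[i]]
        for y in years:
            rows_sid.append(sid[i])
            rows_hid.append(hid[i])
            rows_year.append(int(y))
            rows_amt.append(w12 * cpi[int(y)] / base)
    return pd.DataFrame({
        "subject_id": rows_sid,
        "household_id": rows_hid,
        "year": rows_year,
        "net_worth_nominal": np.round(rows_amt, 2),
    })


def generate_reference_panel(config: SyntheticConfig, n: int = 10_000) -> pd.DataFrame:
    """NHANES-like reference panel (age, sex, obesity flag, biomarkers).

    Biomarkers follow the configured linear age model with no latent-aging
    term (the reference defines the age norm). Includes a young, healthy
    subpopulation (nonobese, ages 20-30) used to train the homeostatic
    dysregulation measure.
    """
    config.validate()
    lo, hi = config.reference_age_range
    if lo > 20.0 or hi < 30.0:
        raise ConfigError(
            f"reference_age_range {config.reference_age_range} must contain [20, 30]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    age = np.round(rng.uniform(lo, hi, size=n), 1)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    obese = (rng.random(n) < config.obesity_prob).astype(int)
    data = {"age": age, "sex": sex, "obese": obese}
    for spec in config.biomarker_specs:
        vals = (spec.intercept + spec.age_slope * age
                + spec.resid_sd * rng.standard_normal(n))
        data[spec.name] = np.exp(vals) if spec.log_scale else vals
    return pd.DataFrame(data)


def simulate_drm_data(
    n: int,
    w: float,
    diagonal_means: Sequence[float],
    lam: float = 0.0,
    noise_sd: float = 1.0,
    couple_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate data from a diagonal reference model.

    Origin and destination categories are drawn independently and uniformly
    (so off-diagonal cells are well populated); the outcome is
    ``w*mu[o] + (1-w)*mu[d] + lam*(d-o) + noise``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    mu = np.asarray(diagonal_means, dtype=float)
    k = len(mu)
    rng = np.random.default_rng(seed)
    o = rng.integers(0, k, size=n)
    d = rng.integers(0, k, size=n)
    m = (d - o).astype(float)
    y = w * mu[o] + (1.0 - w) * mu[d] + lam * m + noise_sd * rng.standard_normal(n)
    n_couples = int(n * couple_fraction) // 2
    hh = np.arange(n)
    hh[: 2 * n_couples] = np.repeat(np.arange(n_couples), 2)
    return pd.DataFrame({
        "y": y,
        "origin_cat": o + 1,
        "dest_cat": d + 1,
        "mobility": m,
        "household_id": hh + 1,
    })
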