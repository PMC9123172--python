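# Methods

`socmob` implements an end-to-end analysis linking life-course social
mobility to biological aging in an older-adult cohort: construction of
blood-chemistry biological-aging measures, socioeconomic origin, attainment
and mobility scores, standardized association models with
household-clustered standard errors and effect-modification tests, and a
diagonal reference model (DRM) decomposition. Because the observational data
this style of analysis is run on (a large US aging survey with a venous
blood study) are access-restricted, the package ships a first-class
synthetic-data generator with known ground truth, and every stage is
validated against planted effects.

## Synthetic cohort model

The generator (`socmob.synthetic`) draws, per subject:

- latent childhood origins `O ~ N(0,1)`;
- a mobility shock `M ~ N(0,1)` independent of `O`;
- latent attainment `A = rho*O + sqrt(1-rho^2)*M` (default `rho = 0.5`), so
  `M` is, up to scale, exactly the residual of `A` on `O` — the quantity the
  residualized-change mobility metric estimates;
- a latent aging outcome
  `L = beta_origins*O + beta_attainment*A + beta_mobility*M + u_h + e`,
  scaled to unit variance, with `u_h` a household random effect shared by
  couples (SD `household_sigma`, default 0.30).

`beta_attainment` is the *direct* attainment effect beyond the origin and
mobility channels; the marginal standardized effects implied by a
configuration are returned by `planted_marginal_effects`. The defaults
(`beta_origins = -0.05`, `beta_attainment = 0`, `beta_mobility = -0.20`)
give marginal effects of about −0.05 for origins, −0.20 for attainment and
−0.20 for residualized-change mobility, the magnitudes typical of wealth-based
mobility analyses in older US cohorts.

Measurements are noisy readouts of the latent structure:

- **Blood chemistries** follow `x_j = q_j + k_j*(age + c*L) + N(0, s_j)`
  with `c = 8` years per SD of `L`; C-reactive protein is generated on the
  log scale and emitted raw. The reference panel uses the same linear age
  model with `L = 0` (the reference defines the age norm).
- **DNAm values** are affine transforms of `L`: clocks are
  `age + 4yr * (sqrt(r)*L + noise)`, and DunedinPoAm is
  `1 + 0.10 * (sqrt(r)*L + noise)` with reliability `r = 0.96`. DunedinPoAm
  is centered at 1 — the benchmark pace of one year of physiological decline
  per calendar year in midlife adults — and the generator's mean is checked
  against that benchmark at n = 10,000 (±0.01).
- **Childhood items** (family finances, father's occupation, hardship coded
  so higher = less hardship, parents' education) each load 0.95 on `O`, with
  completely-at-random missingness (rates 2–10% by item). Parents' years of
  schooling also drive the parental education categories used in
  educational-mobility analysis.
- **Wealth** is household-level: one constant-dollar net worth per household,
  `scale * sinh(A_household + noise)` (so negative net worth occurs),
  emitted as nominal dollars across 2–5 survey waves via a price index.
  Both members of a couple share the household value.

Couples (default half the sample) share a household id, the household
random effect, and household wealth; their latent attainment correlates 0.8
through shared components of `O` (assortative mating, share 0.4) and `M`.

**Why the defaults are signal-rich.** Biomarker slope/noise ratios and DNAm
reliabilities are deliberately high, so the aging algorithms read `L` with
reliability ≈ 0.98. This is required for the generator's core contract —
that the full pipeline recovers a planted standardized mobility effect
within ±0.02 absolute at n = 20,000 — which is incompatible with
simultaneously emulating the modest inter-measure correlations (r ≈ 0.2–0.35)
seen in real cohorts, where each algorithm carries large independent
measurement variance. Passing tests therefore demonstrate correctness of
the pipeline's transformations and inference, not robustness to realistic
measurement attenuation; the noise knobs (`biomarker_specs` residual SDs,
`clock_reliability`, `poam_reliability`, `item_loading`) can be turned down
to study attenuation explicitly. Even at the defaults, the measurement chain
(origins index reliability ≈ 0.99, couple-shared household wealth ≈ 0.97,
KDM readout ≈ 0.98) attenuates a planted −0.20 mobility effect to an
estimated ≈ −0.187; this shortfall is a property of the planted couple
structure, not an estimator defect.

## Biological-aging algorithms

- **KDM Biological Age**: per-biomarker regressions of the chemistry on
  chronological age in the reference panel give `(q_j, k_j, s_j)`; the score
  is the closed-form precision-weighted combination
  `BA = [Σ (x_j - q_j) k_j/s_j² + CA/s_BA²] / [Σ (k_j/s_j)² + 1/s_BA²]`,
  the exact minimizer of the weighted sum of squares (verified against a
  brute-force 1-D minimizer to 1e-8). `s_BA²` uses the Klemera–Doubal
  estimate `mean((BA_E - CA)²) - ((1-r̄²)/r̄²)·range(CA)²/(12m)` with `r̄`
  the characteristic correlation coefficient, floored at 1e-3 (the floor
  binds when the reference panel has no true biological-age dispersion, as
  in the synthetic reference; the score's correlation structure is invariant
  to `s_BA²`, which only rescales the advancement values). An explicit
  override and a no-CA variant (`include_ca=False`) are provided. Biomarkers
  with age slope below 1e-8 are rejected (the slope is a divisor).
- **Homeostatic dysregulation**: biomarkers standardized to the young,
  healthy reference subsample (nonobese, ages 20–30); the score is
  `log(d²)` with `d²` the Mahalanobis squared distance under the subsample
  covariance, floored at 1e-12 before the log so the measure is defined at
  the reference mean. The covariance gets a 1e-8 ridge only if its condition
  number exceeds 1e12 (logged).
- **PhenoAge**: linear predictor over nine chemistries plus age (published
  coefficients shipped as `data/phenoage_levine2018.csv`, with units in the
  file header), Gompertz 10-year mortality risk
  `1 - exp(-exp(xb)·(exp(120γ)-1)/γ)`, inverted through the reference
  risk-age calibration. The age→risk and risk→age maps are exact inverses
  (round trip < 1e-8 over ages 20–100). Boundary risks are clamped at 1e-15
  with a warning.
- **Advancement values** (regression outcomes): PhenoAge and KDM Biological
  Age minus chronological age; DNAm clocks residualized on age in-sample;
  homeostatic dysregulation (not on an age scale) and DunedinPoAm (already
  a rate) pass through.

CRP enters all algorithms on the log scale, floored at 1e-3 mg/dL. No
winsorization of chemistries is applied.

## SES indices

**Origins**: first principal component of the 4×4 correlation matrix of the
childhood items on complete cases, sign anchored so the parents'-education
loading is positive. Missing father's occupation and parents' education are
imputed at cell means (race × 5-year birth cohort × finances-score
quintile), falling back to coarser cells and ultimately the grand mean, with
the fallback level recorded. Factor scores are the *mean* of
loading-weighted standardized items over available items (mean, not sum,
keeps 3- and 4-item scores on one scale); subjects with fewer than 3 items
are missing. Scores become z-scores and percentile ranks within 5-year birth
cohorts (bins anchored at 1900, configurable; average ranks for ties;
singleton cohorts rank 100 with a warning).

**Attainment**: nominal wave wealth → constant 2012 dollars (price-index
ratios; a synthetic index fixture ships for tests) → across-wave mean →
inverse hyperbolic sine → "theta" normalization → z-scores and overall
percentile ranks. The theta step is implemented as a rank-based
inverse-normal transform (Blom offset) followed by least-squares adjustment
for quadratic age and sex, rescaled to unit variance. Normalization
*precedes* adjustment: IHS wealth is strongly bimodal around zero net worth,
and adjusting first then rank-transforming re-introduces age dependence
through the nonlinear rank map; the chosen order makes the output exactly
orthogonal to the age terms while staying monotone in wealth within
(age, sex) strata. A Yeo-Johnson variant is available behind a switch.
Whether attainment percentile ranks should be within-cohort is ambiguous in
this literature; they are computed overall here (configurable via
`percentile_rank_within_cohort`).

**Mobility**: residualized change (residual of attainment z on origins z;
exactly orthogonal to origins) and difference score (attainment z minus
origins z), each also computed on the percentile scale, all z-scored for
effect-size reporting (whole-sample standardization). Educational mobility:
participant category (1 <HS, 2 HS without college degree, 3 college+; a
years→credential map uses ≥16 and ≥12 years) minus parental category (per
parent, percentile of years of schooling within the participant's 5-year
birth cohort, cut at <25th / [25th, 75th] closed / >75th; the higher parent
counts), an integer in [−2, 2].

## Association models

OLS with the outcome standardized and (for the mobility/SES z-scores) the
exposure standardized, so coefficients are in SD-per-SD units and equal
Pearson's r in the no-covariate case. Covariates: centered age, age², sex,
race (White/Black/other), Hispanic ethnicity, and both age terms crossed
with each demographic. Standard errors are CR1 cluster-robust at the
household level (`G/(G-1)·(n-1)/(n-k)` correction, configurable to CR0),
with a t reference on G−1 degrees of freedom. Effect modification adds
`SES×Z` (and Z's main effect; for sex the main effect is already among the
covariates); Black/White modification restricts the sample to those two
groups and drops the race covariate. Estimation is complete-case per model.
The clustered fit is delegated to statsmodels; an independent numpy
implementation of the sandwich (`cluster_robust_cov`) is kept and tested
against it, and its calibration is verified by simulation (94–96% CI
coverage at n = 2,000 with within-household outcome correlation 0.5, and
uniform interaction p-values under a null effect-modification).

## Diagonal reference model

`E[y|o,d] = w·mu_oo + (1-w)·mu_dd + gamma'X + lambda·(d-o)` with
`w ∈ [0,1]` (an unconstrained search is available behind a flag). Status
categories default to tertiles of the origins and attainment scores. For
fixed `w` the model is linear and solved exactly; the profile over `w` uses
a 21-point grid plus bounded refinement, and tests verify the profiled
objective beats a 101-point grid. `lambda` gets a seeded household-bootstrap
SE (default 500 resamples).

**Identification caveat.** When the diagonal means are (near-)linear in the
category index — as they are for quantile categories of normally
distributed scores with a linear outcome model — the linear mobility term
is collinear with the `w`-weighted status structure, and `(w, lambda)` are
only weakly jointly identified: the fit may push `w` to a boundary while
`lambda` absorbs the linear status gradient, leaving fitted cell means (and
the total status+mobility effect) stable. The mobility-effect recovery
simulation therefore uses curved diagonal means (−0.5, 0.25, 0.5), where
`lambda` is identified (recovered within ±0.04 at n = 5,000); `w`-recovery
is simulated without the mobility term. Real DRM applications should check
the curvature of the estimated diagonal means before interpreting `lambda`.

## Problem sizes and numerical choices

Recovery and calibration simulations use n = 20,000 subjects × 10 seeds
(mobility-effect recovery), 500 replicates at n = 2,000 (CI coverage), 200
replicates at n = 1,000 (interaction-null calibration), and n = 5,000 (DRM),
sizes at which Monte-Carlo error is well below the tolerances being checked.
Tie-breaks use average ranks throughout (permutation-invariant). Degenerate
inputs raise informative errors rather than producing silent output:
all-identical wealth, zero-variance PCA items, constant modifiers,
single-cluster variance requests, all-diagonal DRM data.

## Limitations

- The generator does not emulate survey weights, attrition, mortality
  selection, or reporting bias in retrospective childhood measures; MCAR
  missingness only (mean-based imputation is insensitive to MCAR vs MAR
  only under MCAR).
- The blood-chemistry panel is synthetic in level and slope; PhenoAge output
  is therefore not calibrated to real population values (its monotonicity
  and round-trip properties are what is guaranteed).
- The "theta" wealth normalization and the DRM categorization are explicit
  design choices among several defensible options; both are configurable
  and flagged above.
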