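"""Diagonal reference model (DRM) for separating status from mobility.

Sobel's diagonal reference model expresses the expected outcome of a person
with origin-status category ``o`` and destination-status category ``d`` as a
convex combination of the mean outcomes of the *non-mobile* (diagonal)
members of those categories:

    E[y | o, d] = w * mu_oo + (1 - w) * mu_dd + gamma' X + lambda * m

where ``w`` in [0, 1] is the relative salience of origin versus destination
status, the ``mu_kk`` are diagonal means, ``X`` are optional covariates, and
the optional linear mobility term ``lambda * m`` (m = destination index
minus origin index) carries any effect of movement itself beyond the status
mix. For fixed ``w`` the model is linear and solved exactly by least
squares; the fit profiles that inner solution over ``w`` with a bounded 1-D
optimization plus a grid refinement to guard against local minima. Standard
errors for the mobility coefficient come from a cluster (household)
bootstrap, because the profiled estimator's asymptotics are awkward under
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["DRMFit", "categorize_status", "fit_drm", "drm_mobility_effect",
           "MobilityEffect"]


def categorize_status(origins_score, attainment_score, k: int = 3):
    """Quantile categories (1..k) of the continuous origin and destination
    scores. Raises if ties leave a bin empty."""
    if k < 2:
        raise ValueError("k must be >= 2")
    out = []
    for name, score in (("origin", origins_score), ("destination", attainment_score)):
        score = pd.Series(score).astype(float)
        try:
            cat = pd.qcut(score, k, labels=False)
        except ValueError as err:
            raise ValueError(
                f"could not form {k} nonempty {name} categories (ties); "
                "try a smaller k") from err
        out.append((cat + 1).astype("Int64"))
    return tuple(out)


@dataclass
class DRMFit:
    w: float
    diagonal_means: np.ndarray
    covariate_coefs: np.ndarray
    mobility_coefficient: float | None
    sse: float
    n: int
    n_evaluations: int
    converged: bool = True
    w_trace: list = field(default_factory=list, repr=False)

    def predict_cell(self, origin_cat: int, dest_cat: int) -> float:
        mu = self.diagonal_means
        return self.w * mu[origin_cat - 1] + (1 - self.w) * mu[dest_cat - 1]

    def to_dict(self) -> dict:
        return {
            "w": self.w,
            "diagonal_means": self.diagonal_means.tolist(),
            "covariate_coefs": self.covariate_coefs.tolist(),
            "mobility_coefficient": self.mobility_coefficient,
            "sse": self.sse, "n": self.n, "converged": self.converged,
        }


def _drm_design(w, o_idx, d_idx, k, covariates, mobility):
    n = len(o_idx)
    D = np.zeros((n, k))
    D[np.arange(n), o_idx] += w
    D[np.arange(n), d_idx] += 1.0 - w
    cols = [D]
    if covariates is not None:
        cols.append(covariates)
    if mobility is not None:
        cols.append(mobility[:, None])
    return np.hstack(cols)


def fit_drm(
    outcome,
    origin_cat,
    dest_cat,
    covariates: np.ndarray | None = None,
    include_mobility_term: bool = False,
    w_grid_points: int = 21,
    constrain_w: bool = True,
) -> DRMFit:
    """Profiled least-squares fit of the diagonal reference model.

    For fixed ``w`` the diagonal means, covariate coefficients, and mobility
    coefficient are exact least-squares solutions; the outer problem
    minimizes the profiled sum of squares over ``w`` in [0, 1] (coarse grid,
    then bounded refinement around the best bracket). ``constrain_w=False``
    widens the search to [-1, 2] for diagnostic use.

    Covariates, if given, must not contain a constant column (the diagonal
    means absorb the intercept).
    """
    y = np.asarray(outcome, float)
    o = np.asarray(pd.Series(origin_cat).astype(int)) - 1
    d = np.asarray(pd.Series(dest_cat).astype(int)) - 1
    k = int(max(o.max(), d.max())) + 1
    counts = np.bincount(np.concatenate([o, d]), minlength=k)
    if np.any(counts == 0):
        raise ValueError(f"empty status categor(ies): {np.where(counts == 0)[0] + 1}")
    if np.all(o == d):
        raise ValueError(
            "all observations lie on the diagonal; the origin/destination "
            "weight w is unidentified")
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if np.any(np.ptp(covariates, axis=0) == 0):
            raise ValueError("covariates must not contain a constant column")
    mob = (d - o).astype(float) if include_mobility_term else None

    n_eval = 0
    best_sse = [np.inf]

    def profiled_sse(w: float) -> float:
        nonlocal n_eval
        n_eval += 1
        X = _drm_design(w, o, d, k, covariates, mob)
        _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res[0]) if res.size else float(
            np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
        best_sse[0] = min(best_sse[0], sse)
        return sse

    lo, hi = (0.0, 1.0) if constrain_w else (-1.0, 2.0)
    grid = np.linspace(lo, hi, w_grid_points)
    grid_sse = np.array([profiled_sse(w) for w in grid])
    i = int(np.argmin(grid_sse))
    bracket = (grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)])
    opt = minimize_scalar(profiled_sse, bounds=bracket, method="bounded",
                          options={"xatol": 1e-8})
    w_hat, sse_hat = (float(opt.x), float(opt.fun))
    if grid_sse[i] < sse_hat:  # keep the grid point if refinement regressed
        w_hat, sse_hat = float(grid[i]), float(grid_sse[i])

    X = _drm_design(w_hat, o, d, k, covariates, mob)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    mu = beta[:k]
    n_cov = 0 if covariates is None else covariates.shape[1]
    gamma = beta[k:k + n_cov]
    lam = float(beta[-1]) if include_mobility_term else None
    return DRMFit(w=w_hat, diagonal_means=mu, covariate_coefs=gamma,
                  mobility_coefficient=lam, sse=sse_hat, n=len(y),
                  n_evaluations=n_eval, converged=bool(opt.success),
                  w_trace=list(zip(grid.tolist(), grid_sse.tolist())))


@dataclass
class MobilityEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot_quantiles: dict

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("estimate", "se", "ci_low", "ci_high", "n_boot",
                 "boot_quantiles")}


def drm_mobility_effect(
    outcome,
    origin_cat,
    dest_cat,
    households,
    covariates: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[DRMFit, MobilityEffect]:
    """Linear mobility coefficient lambda with a cluster-bootstrap SE.

    Households are resampled with replacement (default 500 resamples,
    seeded); the SE is the bootstrap standard deviation and the CI the
    2.5/97.5 percentile interval.
    """
    y = np.asarray(outcome, float)
    o = np.asarray(pd.Series(origin_cat).astype(int))
    d = np.asarray(pd.Series(dest_cat).astype(int))
    hh = np.asarray(households)
    fit = fit_drm(y, o, d, covariates=covariates, include_mobility_term=True)
    if not fit.converged:
        raise RuntimeError(
            f"DRM fit did not converge; w trace: {fit.w_trace}")

    codes, uniq = pd.factorize(hh)
    members = [np.where(codes == g)[0] for g in range(len(uniq))]
    rng = np.random.default_rng(seed)
    lams = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.integers(0, len(members), size=len(members))
        idx = np.concatenate([members[g] for g in draw])
        bf = fit_drm(y[idx], o[idx], d[idx],
                     covariates=None if covariates is None else covariates[idx],
                     include_mobility_term=True)
        lams[b] = bf.mobility_coefficient
    qs = np.percentile(lams, [2.5, 25, 50, 75, 97.5])
    effect = MobilityEffect(
        estimate=float(fit.mobility_coefficient),
        se=float(np.std(lams, ddof=1)),
        ci_low=float(qs[0]), ci_high=float(qs[-1]), n_boot=n_boot,
        boot_quantiles={"2.5": qs[0], "25": qs[1], "50": qs[2],
                        "75": qs[3], "97.5": qs[4]})
    return fit, effect
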