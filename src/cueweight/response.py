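"""Linear response-speed model and estimation of the integration weight w.

Trial-wise response speed is modeled as an affine function of the
integrated expectancy held *before* the trial's outcome is observed:

    RS(t) = zeta1_valid   + zeta2_valid   * p_int(t-1)        (valid)
    RS(t) = zeta1_invalid + zeta2_invalid * (1 - p_int(t-1))  (invalid)

with homoscedastic Gaussian noise of SD sigma on RS.  The intercepts
set the overall speed level per cue-validity condition; the slopes
measure how strongly speed tracks the learned expectancy.

Estimation is profiled maximum likelihood: w is the only nonlinear
parameter, so for each candidate w on a grid the zetas are solved in
closed form by least squares within each validity condition and sigma
from the residual variance; the grid optimum is then refined by bounded
1-D search.

Model evidence ("marginal", the default) integrates the bounded
model-specific parameters out under their natural uniform priors — w
over [0, 1] for the learning model, each block's p_const over [0, 1]
for the constant model, mirroring the observer's own uniform Beta
prior — so each such parameter pays its exact Occam factor, and
BIC-penalizes the five shared parameters (intercepts, slopes, sigma),
which are common to both models and cancel in any comparison.  Plain
BIC and a Hessian-based Laplace correction are also available; BIC's
unit-information penalty markedly over-penalizes the constant model's
bounded block-level parameters, each informed by only one block of
trials.

Two observation models are provided for model comparison:

- the Bayesian-learner model above, with a single w shared across the
  concatenated blocks of one subject and modality (6 free parameters);
- a constant-predictability alternative with no trial-by-trial
  learning: one free block-constant level p_const per block replaces
  the trajectory (#blocks + 5 free parameters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: conditions with fewer kept trials than this get an intercept-only fit
MIN_TRIALS_FOR_SLOPE = 3

#: minimum kept trials for a fitting unit to be attempted at all
MIN_TRIALS_PER_UNIT = 6

_SIGMA2_FLOOR = 1e-18
_FLAT_LOGLIK_TOL = 1e-9


@dataclass(frozen=True)
class ResponseParams:
    """Affine RS-model parameters (all in 1/s; slopes per unit probability)."""

    zeta1_valid: float
    zeta2_valid: float
    zeta1_invalid: float
    zeta2_invalid: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class WeightFit:
    """Result of fitting the Bayesian-learner response model to one unit."""

    w_hat: float
    params: ResponseParams | None
    log_likelihood: float
    log_evidence: float
    n_trials_used: int
    fitting_unit: tuple
    k_params: int = 0
    flags: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def ok(self) -> bool:
        return self.converged and "too_few_trials" not in self.flags


@dataclass
class ConstantModelFit:
    """Result of fitting the constant-predictability alternative model."""

    p_const: dict
    params: ResponseParams | None
    log_likelihood: float
    log_evidence: float
    n_trials_used: int
    fitting_unit: tuple
    k_params: int = 0
    flags: list[str] = field(default_factory=list)
    converged: bool = True

    @property
    def ok(self) -> bool:
        return self.converged and "too_few_trials" not in self.flags


def predicted_rs(p_int_prior, validity, params: ResponseParams):
    """Forward prediction of mean RS from the integrated expectancy."""
    p = np.asarray(p_int_prior, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_int_prior must lie in [0, 1]")
    valid = np.asarray(validity) == "valid" if not np.issubdtype(
        np.asarray(validity).dtype, np.bool_
    ) else np.asarray(validity)
    out = np.where(
        valid,
        params.zeta1_valid + params.zeta2_valid * p,
        params.zeta1_invalid + params.zeta2_invalid * (1.0 - p),
    )
    if out.ndim == 0:
        return float(out)
    return out


def gaussian_loglik(rs_observed, rs_predicted, sigma: float) -> float:
    """Sum of independent normal log-densities of the RS residuals."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    obs = np.asarray(rs_observed, dtype=float)
    pred = np.asarray(rs_predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    n = obs.size
    sse = float(np.sum((obs - pred) ** 2))
    return -0.5 * n * math.log(2.0 * math.pi * sigma**2) - sse / (2.0 * sigma**2)


def log_evidence(
    log_lik: float,
    k_params: int,
    n_obs: int,
    method: str = "bic",
    hessian: np.ndarray | None = None,
) -> float:
    """Penalized log model evidence.

    ``bic``: log_lik - (k/2) ln n.  ``laplace``: log_lik + (k/2) ln 2*pi
    - (1/2) ln det H, with H the observed information (Hessian of the
    negative log-likelihood) at the optimum; falls back to BIC when the
    Hessian is missing or not positive definite.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    bic = log_lik - 0.5 * k_params * math.log(n_obs)
    if method == "bic":
        return bic
    if method != "laplace":
        raise ValueError(f"unknown evidence method: {method!r}")
    if hessian is None:
        logger.warning("laplace evidence requested without Hessian; using BIC")
        return bic
    H = np.asarray(hessian, dtype=float)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        logger.warning("laplace Hessian not positive definite; using BIC")
        return bic
    return log_lik + 0.5 * k_params * math.log(2.0 * math.pi) - 0.5 * logdet


# ---------------------------------------------------------------------------
# profiled least squares machinery


def _unit_arrays(unit: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    for col in ("p_vis_prior", "p_tac_prior", "modality", "validity", "rs"):
        if col not in unit.columns:
            raise ValueError(f"fitting unit missing column {col!r}")
    is_vis = (unit["modality"] == "visual").to_numpy()
    p_vis = unit["p_vis_prior"].to_numpy(dtype=float)
    p_tac = unit["p_tac_prior"].to_numpy(dtype=float)
    p_own = np.where(is_vis, p_vis, p_tac)
    p_other = np.where(is_vis, p_tac, p_vis)
    valid = (unit["validity"] == "valid").to_numpy()
    rs = unit["rs"].to_numpy(dtype=float)
    if np.any(~np.isfinite(rs)):
        raise ValueError("rs contains non-finite values; filter trials first")
    return p_own, p_other, valid, rs


def _ls_condition(
    x: np.ndarray, y: np.ndarray, allow_slope: bool = True
) -> tuple[float, float, float, bool]:
    """Least-squares intercept/slope for one validity condition.

    Returns (intercept, slope, sse, slope_free).  The slope is fixed at
    zero when the condition is too sparse or the predictor degenerate.
    """
    n = len(y)
    if n == 0:
        return 0.0, 0.0, 0.0, False
    varx = float(np.var(x))
    if not allow_slope or n < MIN_TRIALS_FOR_SLOPE or varx < 1e-12:
        intercept = float(np.mean(y))
        sse = float(np.sum((y - intercept) ** 2))
        return intercept, 0.0, sse, False
    mx, my = float(np.mean(x)), float(np.mean(y))
    slope = float(np.sum((x - mx) * (y - my)) / np.sum((x - mx) ** 2))
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    return intercept, slope, float(np.sum(resid**2)), True


def _profile_at_w(
    w: float,
    p_own: np.ndarray,
    p_other: np.ndarray,
    valid: np.ndarray,
    rs: np.ndarray,
) -> tuple[float, ResponseParams, int]:
    """Closed-form zetas and sigma at fixed w; returns (loglik, params, k)."""
    p_int = w * p_own + (1.0 - w) * p_other
    z1v, z2v, sse_v, free_v = _ls_condition(p_int[valid], rs[valid])
    z1i, z2i, sse_i, free_i = _ls_condition(1.0 - p_int[~valid], rs[~valid])
    n = len(rs)
    sigma2 = max((sse_v + sse_i) / n, _SIGMA2_FLOOR)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    params = ResponseParams(z1v, z2v, z1i, z2i, math.sqrt(sigma2))
    # free parameters: w, two intercepts, free slopes, sigma
    k = 1 + 2 + int(free_v) + int(free_i) + 1
    return loglik, params, k


def _fd_hessian(f: Callable[[np.ndarray], float], x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    k = len(x0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def _laplace_hessian_weighting(
    w: float,
    params: ResponseParams,
    p_own: np.ndarray,
    p_other: np.ndarray,
    valid: np.ndarray,
    rs: np.ndarray,
) -> np.ndarray | None:
    # curvature of the smooth extension; a boundary optimum (w at 0 or
    # 1) is treated as interior, a standard half-Gaussian approximation
    theta0 = np.array(
        [
            w,
            params.zeta1_valid,
            params.zeta2_valid,
            params.zeta1_invalid,
            params.zeta2_invalid,
            math.log(params.sigma),
        ]
    )

    def negloglik(theta: np.ndarray) -> float:
        p_int = theta[0] * p_own + (1.0 - theta[0]) * p_other
        pred = np.where(
            valid,
            theta[1] + theta[2] * p_int,
            theta[3] + theta[4] * (1.0 - p_int),
        )
        sigma = math.exp(theta[5])
        return -gaussian_loglik(rs, pred, sigma)

    return _fd_hessian(negloglik, theta0)


def _laplace_hessian_constant(
    p: np.ndarray,
    params: ResponseParams,
    block_codes: np.ndarray,
    valid: np.ndarray,
    rs: np.ndarray,
) -> np.ndarray | None:
    theta0 = np.concatenate(
        [
            p,
            [
                params.zeta1_valid,
                params.zeta2_valid,
                params.zeta1_invalid,
                params.zeta2_invalid,
                math.log(params.sigma),
            ],
        ]
    )
    nb = len(p)

    def negloglik(theta: np.ndarray) -> float:
        pb = theta[:nb]
        x = np.where(valid, pb[block_codes], 1.0 - pb[block_codes])
        pred = np.where(
            valid,
            theta[nb] + theta[nb + 1] * x,
            theta[nb + 2] + theta[nb + 3] * x,
        )
        sigma = math.exp(theta[nb + 4])
        return -gaussian_loglik(rs, pred, sigma)

    return _fd_hessian(negloglik, theta0)


#: number of shared response-model parameters (2 intercepts, 2 slopes, sigma)
N_SHARED_PARAMS = 5


def fit_weighting(
    unit: pd.DataFrame,
    grid_step: float = 0.01,
    evidence: str = "marginal",
    w_bounds: tuple[float, float] = (0.0, 1.0),
    fitting_unit: tuple | None = None,
) -> WeightFit:
    """Estimate (w, zetas, sigma) for one fitting unit of kept trials.

    The unit is typically one subject x block x modality (or the
    concatenated blocks of one subject x modality); belief columns must
    come from trajectories over the *full* presented sequence.  Too-few
    trials yield a flagged failure record rather than an exception so a
    cohort run survives sparse units.
    """
    if fitting_unit is None:
        fitting_unit = _infer_unit(unit)
    n = len(unit)
    if n < MIN_TRIALS_PER_UNIT:
        return WeightFit(
            w_hat=float("nan"),
            params=None,
            log_likelihood=float("nan"),
            log_evidence=float("nan"),
            n_trials_used=n,
            fitting_unit=fitting_unit,
            flags=["too_few_trials"],
            converged=False,
        )
    p_own, p_other, valid, rs = _unit_arrays(unit)
    lo, hi = w_bounds
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    logliks = np.array(
        [_profile_at_w(w, p_own, p_other, valid, rs)[0] for w in grid]
    )
    flags: list[str] = []
    flat = float(np.ptp(logliks)) < _FLAT_LOGLIK_TOL * max(
        1.0, float(np.max(np.abs(logliks)))
    )
    if len(grid) == 1:
        w_hat = float(grid[0])
    elif flat:
        # w enters only through the slopes; flat likelihood means the
        # slopes vanish (or the two trajectories coincide)
        w_hat = 0.5
        flags.append("w_unidentified")
    else:
        i = int(np.argmax(logliks))
        bracket = (grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)])
        if bracket[0] < bracket[1]:
            res = minimize_scalar(
                lambda w: -_profile_at_w(w, p_own, p_other, valid, rs)[0],
                bounds=bracket,
                method="bounded",
                options={"xatol": 1e-6},
            )
            w_hat = float(res.x)
            if -res.fun < logliks[i]:  # keep the grid point if refinement lost
                w_hat = float(grid[i])
        else:
            w_hat = float(grid[i])
    loglik, params, k = _profile_at_w(w_hat, p_own, p_other, valid, rs)
    if evidence == "marginal":
        # integrate w out under a uniform prior on [lo, hi] (profiled
        # zetas/sigma), then BIC-penalize the shared parameters
        marginal_w = float(
            logsumexp(logliks) + math.log(grid_step) - math.log(hi - lo)
        )
        ev = log_evidence(marginal_w, N_SHARED_PARAMS, n, method="bic")
    elif evidence == "laplace":
        hessian = _laplace_hessian_weighting(w_hat, params, p_own, p_other, valid, rs)
        k_lap = hessian.shape[0] if hessian is not None else k
        ev = log_evidence(loglik, k_lap, n, method="laplace", hessian=hessian)
    else:
        ev = log_evidence(loglik, k, n, method=evidence)
    return WeightFit(
        w_hat=w_hat,
        params=params,
        log_likelihood=loglik,
        log_evidence=ev,
        n_trials_used=n,
        fitting_unit=fitting_unit,
        k_params=k,
        flags=flags,
    )


def fit_bayesian_concatenated(
    unit: pd.DataFrame,
    grid_step: float = 0.01,
    evidence: str = "marginal",
    w_bounds: tuple[float, float] = (0.0, 1.0),
) -> WeightFit:
    """Fit a single (w, zetas, sigma) across all blocks of one subject x modality.

    Beliefs still reset at every block boundary (encoded in the belief
    columns); only the response-model parameters are shared.
    """
    fitting_unit = _infer_unit(unit, concatenated=True)
    return fit_weighting(
        unit,
        grid_step=grid_step,
        evidence=evidence,
        w_bounds=w_bounds,
        fitting_unit=fitting_unit,
    )


def _infer_unit(unit: pd.DataFrame, concatenated: bool = False) -> tuple:
    subj = unit["subject_id"].iloc[0] if "subject_id" in unit.columns and len(unit) else None
    mod = unit["modality"].iloc[0] if "modality" in unit.columns and len(unit) else None
    if concatenated:
        return (subj, mod, "concatenated")
    block = None
    if "block" in unit.columns and len(unit) and unit["block"].nunique() == 1:
        block = unit["block"].iloc[0]
    return (subj, block, mod)


# ---------------------------------------------------------------------------
# constant-predictability alternative model


def _constant_model_sse(
    p_by_block: np.ndarray,
    block_codes: np.ndarray,
    valid: np.ndarray,
    rs: np.ndarray,
) -> tuple[float, ResponseParams, int]:
    x = np.where(valid, p_by_block[block_codes], 1.0 - p_by_block[block_codes])
    z1v, z2v, sse_v, free_v = _ls_condition(x[valid], rs[valid])
    z1i, z2i, sse_i, free_i = _ls_condition(x[~valid], rs[~valid])
    n = len(rs)
    sigma2 = max((sse_v + sse_i) / n, _SIGMA2_FLOOR)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    params = ResponseParams(z1v, z2v, z1i, z2i, math.sqrt(sigma2))
    k = len(p_by_block) + 2 + int(free_v) + int(free_i) + 1
    return loglik, params, k


def optimal_p_const(
    zetas: ResponseParams, valid: np.ndarray, rs: np.ndarray
) -> float | None:
    """Closed-form block-constant predictability level given the zetas.

    Minimizes the within-block SSE; returns None when both slopes are
    zero (p unidentified).
    """
    z2v, z2i = zetas.zeta2_valid, zetas.zeta2_invalid
    rv = rs[valid] - zetas.zeta1_valid
    ri = rs[~valid] - zetas.zeta1_invalid
    n_v, n_i = int(valid.sum()), int((~valid).sum())
    denom = n_v * z2v**2 + n_i * z2i**2
    if denom < 1e-12:
        return None
    num = z2v * float(rv.sum()) - z2i * float(ri.sum()) + n_i * z2i**2
    return float(np.clip(num / denom, 0.0, 1.0))


def _constant_marginal_loglik(
    params: ResponseParams,
    p_hat: np.ndarray,
    block_codes: np.ndarray,
    valid: np.ndarray,
    rs: np.ndarray,
    n_grid: int = 401,
) -> float:
    """Log likelihood with each block's p_const integrated over U(0, 1).

    At the fitted shared (zetas, sigma) the per-block SSE is quadratic
    in p, so the block marginals factorize; each is evaluated on a
    p-grid.
    """
    sigma2 = params.sigma**2
    grid = np.linspace(0.0, 1.0, n_grid)
    step = grid[1] - grid[0]
    total = 0.0
    for b in np.unique(block_codes):
        mask = block_codes == b
        v = valid[mask]
        rv = rs[mask][v] - params.zeta1_valid
        u = rs[mask][~v] - params.zeta1_invalid - params.zeta2_invalid
        a = len(rv) * params.zeta2_valid**2 + len(u) * params.zeta2_invalid**2
        bq = -2.0 * params.zeta2_valid * rv.sum() + 2.0 * params.zeta2_invalid * u.sum()
        c = float((rv**2).sum() + (u**2).sum())
        nb = int(mask.sum())
        ll_grid = (
            -0.5 * nb * math.log(2.0 * math.pi * sigma2)
            - (a * grid**2 + bq * grid + c) / (2.0 * sigma2)
        )
        total += float(logsumexp(ll_grid) + math.log(step))
    return total


def fit_constant_model(
    unit: pd.DataFrame,
    evidence: str = "marginal",
    max_iter: int = 500,
    tol: float = 1e-10,
) -> ConstantModelFit:
    """Fit the no-learning alternative: one constant level per block.

    Predicted RS uses a free block-constant p_const in place of the
    learner's trajectory; zetas and sigma are shared across blocks.
    Fitted by coordinate descent alternating closed-form least squares
    for the zetas with the closed-form per-block optimum for p_const
    (each step lowers the SSE, so the iteration converges).
    """
    fitting_unit = _infer_unit(unit, concatenated=True)
    n = len(unit)
    if n < MIN_TRIALS_PER_UNIT:
        return ConstantModelFit(
            p_const={},
            params=None,
            log_likelihood=float("nan"),
            log_evidence=float("nan"),
            n_trials_used=n,
            fitting_unit=fitting_unit,
            flags=["too_few_trials"],
            converged=False,
        )
    for col in ("block", "validity", "rs"):
        if col not in unit.columns:
            raise ValueError(f"fitting unit missing column {col!r}")
    blocks = np.array(sorted(unit["block"].unique()))
    block_codes = np.searchsorted(blocks, unit["block"].to_numpy())
    valid = (unit["validity"] == "valid").to_numpy()
    rs = unit["rs"].to_numpy(dtype=float)
    n_blocks = len(blocks)

    def descend(p0: np.ndarray):
        p = p0.copy()
        flags: list[str] = []
        converged = False
        loglik, params, k = _constant_model_sse(p, block_codes, valid, rs)
        for _ in range(max_iter):
            p_new = p.copy()
            unidentified = False
            for b in range(n_blocks):
                mask = block_codes == b
                opt = optimal_p_const(params, valid[mask], rs[mask])
                if opt is None:
                    unidentified = True
                else:
                    p_new[b] = opt
            loglik_new, params_new, k = _constant_model_sse(
                p_new, block_codes, valid, rs
            )
            delta = abs(loglik_new - loglik) + float(np.max(np.abs(p_new - p)))
            p, params, loglik = p_new, params_new, loglik_new
            if unidentified:
                flags.append("p_unidentified")
                converged = True
                break
            if delta < tol:
                converged = True
                break
        if not converged:
            flags.append("max_iter")
        return loglik, params, k, p, flags, converged

    # multi-start: the SSE surface is bilinear in (zetas, p) and the
    # coordinate descent can stall, so start from the empirical valid
    # fraction and from both orientations of the valid-cell means
    empirical = np.array(
        [valid[block_codes == b].mean() for b in range(n_blocks)], dtype=float
    )
    starts = [empirical]
    cell_means = np.array(
        [
            rs[(block_codes == b) & valid].mean()
            if np.any((block_codes == b) & valid)
            else rs[block_codes == b].mean()
            for b in range(n_blocks)
        ]
    )
    span = float(np.ptp(cell_means))
    if span > 1e-12:
        scaled = 0.1 + 0.8 * (cell_means - cell_means.min()) / span
        starts += [scaled, 1.0 - scaled]
    loglik, params, k, p, flags, converged = max(
        (descend(p0) for p0 in starts), key=lambda r: r[0]
    )
    if evidence == "marginal":
        marginal_ll = _constant_marginal_loglik(params, p, block_codes, valid, rs)
        ev = log_evidence(marginal_ll, N_SHARED_PARAMS, n, method="bic")
    elif evidence == "laplace":
        hessian = _laplace_hessian_constant(p, params, block_codes, valid, rs)
        k_lap = hessian.shape[0] if hessian is not None else k
        ev = log_evidence(loglik, k_lap, n, method="laplace", hessian=hessian)
    else:
        ev = log_evidence(loglik, k, n, method=evidence)
    return ConstantModelFit(
        p_const={int(b): float(pv) for b, pv in zip(blocks, p)},
        params=params,
        log_likelihood=loglik,
        log_evidence=ev,
        n_trials_used=n,
        fitting_unit=fitting_unit,
        k_params=k,
        flags=sorted(set(flags)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# cohort-level convenience drivers


def fit_cohort_blockwise(
    labeled: pd.DataFrame, grid_step: float = 0.01, evidence: str = "marginal"
) -> dict[tuple, WeightFit]:
    """Per-(subject, block, modality) weighting fits over a labeled table.

    ``labeled`` must carry belief columns (from the full sequence) and
    ``exclusion_reason``; only kept trials enter the likelihood.
    """
    kept = labeled[labeled["exclusion_reason"] == "kept"]
    fits: dict[tuple, WeightFit] = {}
    for (subj, block, mod), grp in kept.groupby(
        ["subject_id", "block", "modality"], sort=True
    ):
        fits[(subj, block, mod)] = fit_weighting(
            grp, grid_step=grid_step, evidence=evidence,
            fitting_unit=(subj, block, mod),
        )
    logger.info("fit_cohort_blockwise: fitted %d units", len(fits))
    return fits


def fit_cohort_concatenated(
    labeled: pd.DataFrame, grid_step: float = 0.01, evidence: str = "marginal"
) -> tuple[dict[tuple, WeightFit], dict[tuple, ConstantModelFit]]:
    """Concatenated Bayesian-learner and constant-model fits per subject x modality."""
    kept = labeled[labeled["exclusion_reason"] == "kept"]
    bayes: dict[tuple, WeightFit] = {}
    const: dict[tuple, ConstantModelFit] = {}
    for (subj, mod), grp in kept.groupby(["subject_id", "modality"], sort=True):
        bayes[(subj, mod)] = fit_bayesian_concatenated(
            grp, grid_step=grid_step, evidence=evidence
        )
        const[(subj, mod)] = fit_constant_model(grp, evidence=evidence)
    logger.info(
        "fit_cohort_concatenated: fitted %d subject x modality units", len(bayes)
    )
    return bayes, const
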