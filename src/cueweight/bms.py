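"""Random-effects Bayesian model selection over per-subject log evidences.

The group is modeled as drawing each subject's generative model from a
multinomial with unknown frequencies r ~ Dirichlet(alpha0); the
variational posterior over (r, model assignments) is obtained by
iterating the standard fixed-point updates.  The exceedance probability
(XP) of model k is the posterior probability that r_k exceeds every
other frequency, estimated by seeded Monte Carlo over the posterior
Dirichlet (a closed-form Beta integral exists for K = 2 and is exposed
for cross-checking).  The Bayesian omnibus risk (BOR) is the posterior
probability that all models are equally frequent, computed from the
variational free energies of the random-effects model and the
equal-frequency null; the protected exceedance probability is

    PXP_k = XP_k * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

_EPS = 1e-32


@dataclass
class BMSResult:
    """Posterior summary of a random-effects model comparison."""

    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    converged: bool = True
    n_iter: int = 0
    model_names: tuple | None = None


def exceedance_probability(
    alpha: np.ndarray, n_samples: int = 1_000_000, rng=None
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior."""
    rng = np.random.default_rng(rng)
    alpha = np.asarray(alpha, dtype=float)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    counts = np.bincount(winners, minlength=len(alpha))
    return counts / n_samples


def xp_beta_exact(alpha: np.ndarray) -> np.ndarray:
    """Closed-form exceedance probabilities for exactly two models.

    P(r_1 > r_2) = P(r_1 > 1/2) with r_1 ~ Beta(alpha_1, alpha_2).
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (2,):
        raise ValueError("closed form requires exactly 2 models")
    x1 = beta_dist.sf(0.5, alpha[0], alpha[1])
    return np.array([x1, 1.0 - x1])


def protected_xp(xp: np.ndarray, bor: float) -> np.ndarray:
    """Average the exceedance probabilities with chance, weighted by BOR."""
    xp = np.asarray(xp, dtype=float)
    k = len(xp)
    return xp * (1.0 - bor) + bor / k


def _free_energy_rfx(
    L: np.ndarray, g: np.ndarray, alpha: np.ndarray, alpha0: np.ndarray
) -> float:
    """Variational free energy of the random-effects model."""
    elog_r = digamma(alpha) - digamma(alpha.sum())
    sqf = (
        gammaln(alpha).sum()
        - gammaln(alpha.sum())
        - float(((alpha - 1.0) * elog_r).sum())
    )
    sqm = -float(np.sum(g * np.log(g + _EPS)))
    elj = (
        gammaln(alpha0.sum())
        - gammaln(alpha0).sum()
        + float(((alpha0 - 1.0) * elog_r).sum())
        + float(np.sum(g * (elog_r[None, :] + L)))
    )
    return elj + sqf + sqm


def _free_energy_null(L: np.ndarray) -> float:
    """Log evidence of the null: every model equally frequent."""
    n, k = L.shape
    return float(np.sum(logsumexp(L, axis=1) - np.log(k)))


def rfx_bms(
    evidence: np.ndarray,
    alpha0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    model_names: tuple | None = None,
) -> BMSResult:
    """Random-effects BMS over an (n_subjects, n_models) log-evidence matrix.

    Iterates the variational updates of the posterior model assignments
    and Dirichlet pseudo-counts (uniform prior alpha0 = 1 per model)
    until the pseudo-counts change by less than ``tol``; exceedance
    probabilities by seeded Monte Carlo over the posterior Dirichlet.
    """
    L = np.asarray(evidence, dtype=float)
    if L.ndim != 2:
        raise ValueError("evidence must be a 2-D (subjects x models) array")
    n, k = L.shape
    if n < 2:
        raise ValueError("group inference requires at least 2 subjects")
    if k < 2:
        raise ValueError("model comparison requires at least 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("evidence matrix contains non-finite entries")
    if alpha0 is None:
        alpha0 = np.ones(k)
    alpha0 = np.asarray(alpha0, dtype=float)

    alpha = alpha0.copy()
    converged = False
    n_iter = 0
    g = np.full((n, k), 1.0 / k)
    for n_iter in range(1, max_iter + 1):
        u = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(u - logsumexp(u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if float(np.max(np.abs(alpha_new - alpha))) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        logger.warning("rfx_bms: no convergence after %d iterations", max_iter)

    expected_freq = alpha / alpha.sum()
    xp = exceedance_probability(alpha, n_samples=n_samples, rng=seed)
    f_rfx = _free_energy_rfx(L, g, alpha, alpha0)
    f_null = _free_energy_null(L)
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))
    pxp = protected_xp(xp, bor)
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_freq=expected_freq,
        xp=xp,
        bor=bor,
        pxp=pxp,
        converged=converged,
        n_iter=n_iter,
        model_names=model_names,
    )


def compare_learning_models(
    bayes_fits: dict,
    const_fits: dict,
    n_samples: int = 1_000_000,
    seed: int | None = None,
) -> dict[str, BMSResult]:
    """Group BMS of the Bayesian learner vs the constant model, per modality.

    Both fit dictionaries are keyed by (subject_id, modality) and must
    cover identical units fitted on identical kept-trial sets (checked
    via ``n_trials_used``).
    """
    if set(bayes_fits) != set(const_fits):
        raise ValueError("fit dictionaries cover different (subject, modality) units")
    results: dict[str, BMSResult] = {}
    modalities = sorted({mod for _, mod in bayes_fits})
    for mod in modalities:
        rows = []
        for (subj, m) in sorted(k for k in bayes_fits if k[1] == mod):
            bf = bayes_fits[(subj, m)]
            cf = const_fits[(subj, m)]
            if bf.n_trials_used != cf.n_trials_used:
                raise ValueError(
                    f"mismatched kept-trial sets for subject {subj!r}, "
                    f"modality {m!r}"
                )
            if not (bf.ok and cf.ok):
                logger.warning(
                    "compare_learning_models: skipping flagged unit (%r, %r)",
                    subj, m,
                )
                continue
            rows.append([bf.log_evidence, cf.log_evidence])
        results[mod] = rfx_bms(
            np.asarray(rows),
            n_samples=n_samples,
            seed=seed,
            model_names=("bayesian", "constant"),
        )
    return results
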