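"""Bayesian ideal observer for block-wise cue-validity learning.

Each target modality has its own Beta-Bernoulli learner over the
probability that the spatial cue is valid.  With a uniform Beta(1, 1)
prior the posterior mean after observing N1 valid and N0 invalid trials
is (N1 + 1) / (N1 + N0 + 2).  Beliefs reset to uniform at the start of
every block (predictability is block-constant) and each learner is
updated only by trials of its own modality — including trials later
excluded from the behavioral analysis, since the cue-target contingency
is observed regardless of response quality.

The trial-wise expectancy entering the response model is the *prior*
probability before the trial's outcome is observed.  The two
modality-specific expectancies are combined linearly,

    p_int = w * p_mod1 + (1 - w) * p_mod2,

where mod1 is the modality of the current target and w in [0, 1] is the
integration weight: w = 0.5 is full averaging (supramodal processing),
w = 1 is fully separate, modality-specific processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import TrialSpec


@dataclass(frozen=True)
class BetaBelief:
    """Beta pseudo-counts over cue validity (uniform prior = (1, 1))."""

    alpha_valid: float = 1.0
    alpha_invalid: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_valid < 1.0 or self.alpha_invalid < 1.0:
            raise ValueError("pseudo-counts must be >= 1 (uniform prior included)")

    def updated(self, valid: bool) -> "BetaBelief":
        if valid:
            return replace(self, alpha_valid=self.alpha_valid + 1.0)
        return replace(self, alpha_invalid=self.alpha_invalid + 1.0)


def posterior_mean(belief: BetaBelief) -> float:
    """Posterior-mean probability of a valid trial."""
    return belief.alpha_valid / (belief.alpha_valid + belief.alpha_invalid)


def integrate(p_mod1, p_mod2, w: float):
    """Weighted linear combination of two modality-specific probabilities.

    ``p_mod1`` is the expectancy for the current target's modality.
    Accepts scalars or arrays.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w={w} outside [0, 1]")
    p1 = np.asarray(p_mod1, dtype=float)
    p2 = np.asarray(p_mod2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = w * p1 + (1.0 - w) * p2
    if out.ndim == 0:
        return float(out)
    return out


def run_observer(
    trials: Sequence[TrialSpec] | Iterable,
) -> pd.DataFrame:
    """Run both modality learners over one block's ordered trials.

    Returns one row per trial with the *prior* posterior means
    ``p_vis_prior`` and ``p_tac_prior`` (the beliefs given trials
    1..t-1), computed before the trial's own outcome updates its
    modality's learner.
    """
    modalities: list[str] = []
    validities: list[str] = []
    for t in trials:
        if isinstance(t, TrialSpec):
            modalities.append(t.modality)
            validities.append(t.validity)
        else:  # mapping-like (e.g. DataFrame row as dict)
            modalities.append(t["modality"])
            validities.append(t["validity"])
    p_vis, p_tac = _trajectory_arrays(np.asarray(modalities), np.asarray(validities))
    return pd.DataFrame(
        {
            "trial_index": np.arange(len(modalities)),
            "modality": modalities,
            "validity": validities,
            "p_vis_prior": p_vis,
            "p_tac_prior": p_tac,
        }
    )


def _trajectory_arrays(
    modalities: np.ndarray, validities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    n = len(modalities)
    p_vis = np.empty(n)
    p_tac = np.empty(n)
    av = ai = tv = ti = 1.0  # visual/tactile valid/invalid pseudo-counts
    for i in range(n):
        p_vis[i] = av / (av + ai)
        p_tac[i] = tv / (tv + ti)
        valid = validities[i] == "valid"
        if modalities[i] == "visual":
            av, ai = (av + 1.0, ai) if valid else (av, ai + 1.0)
        else:
            tv, ti = (tv + 1.0, ti) if valid else (tv, ti + 1.0)
    return p_vis, p_tac


def belief_trajectories(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach prior belief columns to a (possibly multi-subject) trial table.

    Beliefs reset at every block boundary; trials are processed in
    ``trial_index`` order within each (subject, block) group.  All
    presented trials update the learners, so call this *before* any
    behavioral exclusion.
    """
    required = {"block", "trial_index", "modality", "validity"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    keys = ["block"]
    if "subject_id" in trials.columns:
        keys = ["subject_id", "block"]
    out = trials.copy()
    if not out.index.is_unique:
        out = out.reset_index(drop=True)
    out["p_vis_prior"] = np.nan
    out["p_tac_prior"] = np.nan
    for _, idx in out.groupby(keys, sort=False).groups.items():
        grp = out.loc[idx].sort_values("trial_index")
        p_vis, p_tac = _trajectory_arrays(
            grp["modality"].to_numpy(), grp["validity"].to_numpy()
        )
        out.loc[grp.index, "p_vis_prior"] = p_vis
        out.loc[grp.index, "p_tac_prior"] = p_tac
    return out


def integrated_prior(trials: pd.DataFrame, w: float) -> np.ndarray:
    """Per-trial integrated expectancy p_int given the weight w.

    mod1 is each trial's own target modality.  Requires the belief
    columns added by :func:`belief_trajectories`.
    """
    for col in ("p_vis_prior", "p_tac_prior"):
        if col not in trials.columns:
            raise ValueError(f"missing belief column {col!r}; run belief_trajectories")
    is_vis = (trials["modality"] == "visual").to_numpy()
    p_vis = trials["p_vis_prior"].to_numpy(dtype=float)
    p_tac = trials["p_tac_prior"].to_numpy(dtype=float)
    p_own = np.where(is_vis, p_vis, p_tac)
    p_other = np.where(is_vis, p_tac, p_vis)
    return integrate(p_own, p_other, w)
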