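"""Synthetic cohorts with known ground truth, and recovery studies.

The generator composes the forward model end to end: a seeded balanced
trial sequence, the per-modality ideal-observer trajectories, the
w-weighted integrated expectancy, the affine RS observation model, and
Gaussian RS noise.  Defaults mirror the study conditions the analysis
assumes: 21 subjects per cohort who all see the *same* trial sequence
(a fixed sequence is standard for sequential-learning designs, so that
every subject faces the same inference problem), intercepts 2.2/2.0
1/s (mean RT near 450 ms), expectancy slopes 0.5 1/s, and RS noise
SD 0.2 1/s.

Two generating models are available: the Bayesian learner (trial-wise
trajectory with a true w) and the constant-predictability alternative
(block-constant expectancies; the default sampler draws them
independently of the realized cue-validity stream, since a subject who
does no trial-by-trial learning has no access to it), so both
parameter recovery and model recovery can be exercised against known
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign, randomize_trials
from .observer import belief_trajectories
from .preprocess import filter_trials
from .response import (
    ResponseParams,
    fit_cohort_blockwise,
    fit_cohort_concatenated,
    predicted_rs,
)
from .bms import compare_learning_models

logger = logging.getLogger(__name__)

#: study-condition response parameters: valid/invalid intercepts 2.2/2.0
#: 1/s (about 450-500 ms), expectancy slopes 0.5 1/s, RS noise SD 0.2 1/s
DEFAULT_PARAMS = ResponseParams(
    zeta1_valid=2.2,
    zeta2_valid=0.5,
    zeta1_invalid=2.0,
    zeta2_invalid=0.5,
    sigma=0.2,
)

DEFAULT_N_SUBJECTS = 21

#: lower RS bound for generated data (RT <= 5 s), truncating Gaussian tails
RS_FLOOR = 0.2


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one synthetic subject.

    ``w`` may be a scalar (shared across blocks and modalities) or a
    mapping ``(block_index, modality) -> w``.  For the constant
    generating model, ``p_const`` maps ``(block_index, modality)`` to
    the block-constant level; None means "use the design's
    own-modality predictability".
    """

    subject_id: str
    w: float | Mapping[tuple[int, str], float]
    params: ResponseParams = DEFAULT_PARAMS
    generating_model: str = "bayesian"
    p_const: Mapping[tuple[int, str], float] | None = None

    def __post_init__(self) -> None:
        if self.generating_model not in ("bayesian", "constant"):
            raise ValueError(f"unknown generating_model: {self.generating_model!r}")
        for wv in self._w_values():
            if not 0.0 <= wv <= 1.0:
                raise ValueError(f"true w={wv} outside [0, 1]")

    def _w_values(self):
        if isinstance(self.w, Mapping):
            return list(self.w.values())
        return [self.w]

    def w_for(self, block_index: int, modality: str) -> float:
        if isinstance(self.w, Mapping):
            return self.w[(block_index, modality)]
        return float(self.w)


@dataclass
class RecoveryReport:
    """Outcome of a parameter- (and optionally model-) recovery study."""

    units: pd.DataFrame
    median_abs_error: float
    correlation: float
    model_recovery: dict | None = None


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_subject(
    design: ExperimentDesign,
    truth: GroundTruth,
    seed: int,
    sequence_seed: int | None = None,
    error_rate: float = 0.0,
    rs_floor: float = RS_FLOOR,
) -> pd.DataFrame:
    """Simulate one subject's full trial table from known ground truth.

    The trial sequence and the RS noise use seeds derived from ``seed``
    unless ``sequence_seed`` pins the sequence (so a cohort can share
    one sequence while drawing independent noise).  All trials are
    correct unless ``error_rate > 0`` marks a random subset incorrect.
    Identical arguments yield identical tables.
    """
    ss = np.random.SeedSequence(seed)
    seq_ss, noise_ss, err_ss = ss.spawn(3)
    if sequence_seed is None:
        sequence_seed = _derive_seed(seq_ss)
    rng = np.random.default_rng(noise_ss)

    rows = []
    for block_idx, trials in enumerate(randomize_trials(design, sequence_seed)):
        for t in trials:
            rows.append(
                {
                    "subject_id": truth.subject_id,
                    "experiment": design.experiment_id,
                    "block": block_idx,
                    "trial_index": t.global_index,
                    "modality": t.modality,
                    "cue_side": t.cue_side,
                    "target_side": t.target_side,
                    "validity": t.validity,
                    "elevation": t.elevation,
                }
            )
    df = pd.DataFrame(rows)
    df = belief_trajectories(df)

    if truth.generating_model == "bayesian":
        w = np.array(
            [truth.w_for(b, m) for b, m in zip(df["block"], df["modality"])]
        )
        is_vis = (df["modality"] == "visual").to_numpy()
        p_own = np.where(is_vis, df["p_vis_prior"], df["p_tac_prior"])
        p_other = np.where(is_vis, df["p_tac_prior"], df["p_vis_prior"])
        p = w * p_own + (1.0 - w) * p_other
    else:
        block_by_index = {b.block_index: b for b in design.blocks}
        if truth.p_const is not None:
            p = np.array(
                [truth.p_const[(b, m)] for b, m in zip(df["block"], df["modality"])]
            )
        else:
            p = np.array(
                [
                    block_by_index[b].p_valid(m)
                    for b, m in zip(df["block"], df["modality"])
                ]
            )

    mean_rs = predicted_rs(p, df["validity"].to_numpy(), truth.params)
    if np.any(mean_rs <= 0):
        raise ValueError(
            "pathological response parameters: predicted mean RS <= 0"
        )
    rs = mean_rs + truth.params.sigma * rng.standard_normal(len(df))
    low = rs < rs_floor
    if np.any(low):  # resample the truncated tail once, then clamp
        rs[low] = mean_rs[low] + truth.params.sigma * rng.standard_normal(
            int(low.sum())
        )
        rs = np.maximum(rs, rs_floor)
    df["rt_ms"] = 1000.0 / rs

    other_elev = np.where(df["elevation"] == "proximal", "distal", "proximal")
    correct = np.ones(len(df), dtype=bool)
    if error_rate > 0:
        err_rng = np.random.default_rng(err_ss)
        correct = err_rng.random(len(df)) >= error_rate
    df["response"] = np.where(correct, df["elevation"], other_elev)
    df["correct"] = correct
    return df.drop(columns=["p_vis_prior", "p_tac_prior"])


def uniform_w_sampler(
    low: float = 0.5,
    high: float = 1.0,
    params: ResponseParams = DEFAULT_PARAMS,
    generating_model: str = "bayesian",
    p_const_range: tuple[float, float] = (0.1, 0.9),
) -> Callable:
    """Truth sampler drawing one subject-level w ~ Uniform(low, high).

    For the constant generating model each subject also draws an
    independent block-constant expectancy per (block, modality) from
    ``p_const_range``: a subject who does no trial-by-trial learning
    has no access to the realized cue-validity stream, so the held
    level is decoupled from the block's true predictability.
    """

    def sampler(rng: np.random.Generator, subject_id: str, design) -> GroundTruth:
        p_const = None
        if generating_model == "constant":
            p_const = {
                (b.block_index, m): float(rng.uniform(*p_const_range))
                for b in design.blocks
                for m in ("visual", "tactile")
            }
        return GroundTruth(
            subject_id=subject_id,
            w=float(rng.uniform(low, high)),
            params=params,
            generating_model=generating_model,
            p_const=p_const,
        )

    return sampler


def simulate_cohort(
    design: ExperimentDesign,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    truth_sampler: Callable | None = None,
    seed: int = 0,
    error_rate: float = 0.0,
    shared_sequence: bool = True,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Simulate a cohort; every subject sees the same sequence by default.

    Per-subject noise seeds are derived from the master seed, so the
    cohort is reproducible from (design, seed) alone.  Returns the
    concatenated trial table and the ground-truth records.
    """
    if truth_sampler is None:
        truth_sampler = uniform_w_sampler()
    master = np.random.SeedSequence(seed)
    seq_ss, truth_ss, *subject_ss = master.spawn(2 + n_subjects)
    sequence_seed = _derive_seed(seq_ss) if shared_sequence else None
    truth_rng = np.random.default_rng(truth_ss)

    tables = []
    truths = []
    for i in range(n_subjects):
        subject_id = f"S{i:02d}"
        truth = truth_sampler(truth_rng, subject_id, design)
        truths.append(truth)
        tables.append(
            simulate_subject(
                design,
                truth,
                seed=_derive_seed(subject_ss[i]),
                sequence_seed=sequence_seed,
                error_rate=error_rate,
            )
        )
    cohort = pd.concat(tables, ignore_index=True)
    logger.info(
        "simulate_cohort: %d subjects x %d trials (%s)",
        n_subjects,
        design.n_trials_total,
        design.experiment_id,
    )
    return cohort, truths


def _prepare_labeled(cohort: pd.DataFrame) -> pd.DataFrame:
    """Belief trajectories on the full table, then behavioral exclusion."""
    return filter_trials(belief_trajectories(cohort))


def recovery_experiment(
    design: ExperimentDesign,
    w_values: Sequence[float] = (0.5, 0.7, 0.9),
    n_subjects: int = DEFAULT_N_SUBJECTS,
    sigma: float = 0.2,
    seed: int = 0,
    grid_step: float = 0.01,
    params: ResponseParams | None = None,
    include_model_recovery: bool = False,
    unit: str = "concatenated",
) -> RecoveryReport:
    """Parameter-recovery study: simulate, preprocess, fit, tabulate.

    Subjects are assigned true w values cycling through ``w_values``.
    ``unit`` selects the fitting granularity: ``"concatenated"``
    estimates one w per subject and modality across all blocks (the
    truth is subject-level, so this is the matched estimator);
    ``"block"`` fits every (subject, block, modality) cell separately.
    Flagged fits are kept in the unit table (``ok`` False) and excluded
    from the summary statistics rather than dropped silently.
    """
    if unit not in ("concatenated", "block"):
        raise ValueError(f"unknown fitting unit: {unit!r}")
    if params is None:
        params = DEFAULT_PARAMS
    params = ResponseParams(
        params.zeta1_valid,
        params.zeta2_valid,
        params.zeta1_invalid,
        params.zeta2_invalid,
        sigma,
    )

    def sampler(rng, subject_id, _design):
        i = int(subject_id[1:])
        return GroundTruth(
            subject_id=subject_id,
            w=float(w_values[i % len(w_values)]),
            params=params,
        )

    cohort, truths = simulate_cohort(
        design, n_subjects=n_subjects, truth_sampler=sampler, seed=seed
    )
    labeled = _prepare_labeled(cohort)
    truth_by_subject = {t.subject_id: t for t in truths}

    rows = []
    if unit == "block":
        fits = fit_cohort_blockwise(labeled, grid_step=grid_step)
        for (subj, block, mod), fit in fits.items():
            rows.append(
                {
                    "subject_id": subj,
                    "block": block,
                    "modality": mod,
                    "w_true": truth_by_subject[subj].w_for(block, mod),
                    "w_hat": fit.w_hat,
                    "n_trials_used": fit.n_trials_used,
                    "ok": fit.ok,
                    "flags": ";".join(fit.flags),
                }
            )
    else:
        from .response import fit_bayesian_concatenated

        kept = labeled[labeled["exclusion_reason"] == "kept"]
        bayes = {
            (subj, mod): fit_bayesian_concatenated(grp, grid_step=grid_step)
            for (subj, mod), grp in kept.groupby(["subject_id", "modality"], sort=True)
        }
        for (subj, mod), fit in bayes.items():
            rows.append(
                {
                    "subject_id": subj,
                    "block": "all",
                    "modality": mod,
                    "w_true": truth_by_subject[subj].w_for(0, mod),
                    "w_hat": fit.w_hat,
                    "n_trials_used": fit.n_trials_used,
                    "ok": fit.ok,
                    "flags": ";".join(fit.flags),
                }
            )
    units = pd.DataFrame(rows)
    usable = units[units["ok"]]
    err = np.abs(usable["w_hat"] - usable["w_true"])
    corr = float(np.corrcoef(usable["w_true"], usable["w_hat"])[0, 1])
    report = RecoveryReport(
        units=units,
        median_abs_error=float(err.median()),
        correlation=corr,
    )
    if include_model_recovery:
        report.model_recovery = model_recovery_experiment(
            design, n_subjects=n_subjects, sigma=sigma, seed=seed
        )
    return report


def model_recovery_experiment(
    design: ExperimentDesign,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    sigma: float = 0.2,
    seed: int = 0,
    grid_step: float = 0.01,
    n_samples: int = 1_000_000,
    evidence: str = "marginal",
) -> dict:
    """Model-recovery study: can BMS identify the generating model?

    Simulates one cohort from the Bayesian learner (subject-level
    w ~ Uniform(0.5, 1)) and one from the constant-predictability model
    (independent block-constant expectancies per block and modality),
    fits both observation models to each, and runs the group comparison.
    Returns ``{generator: {modality: BMSResult}}`` plus a flat PXP
    table under ``"pxp"``.
    """
    params = ResponseParams(
        DEFAULT_PARAMS.zeta1_valid,
        DEFAULT_PARAMS.zeta2_valid,
        DEFAULT_PARAMS.zeta1_invalid,
        DEFAULT_PARAMS.zeta2_invalid,
        sigma,
    )
    master = np.random.SeedSequence(seed)
    seeds = master.spawn(3)
    out: dict = {"pxp": {}}
    samplers = {
        "bayesian": uniform_w_sampler(params=params),
        "constant": uniform_w_sampler(params=params, generating_model="constant"),
    }
    for (generator, sampler), gen_ss in zip(samplers.items(), seeds):
        cohort, _ = simulate_cohort(
            design,
            n_subjects=n_subjects,
            truth_sampler=sampler,
            seed=_derive_seed(gen_ss),
        )
        labeled = _prepare_labeled(cohort)
        bayes, const = fit_cohort_concatenated(
            labeled, grid_step=grid_step, evidence=evidence
        )
        results = compare_learning_models(
            bayes, const, n_samples=n_samples, seed=_derive_seed(seeds[2])
        )
        out[generator] = results
        model_idx = {"bayesian": 0, "constant": 1}[generator]
        out["pxp"][generator] = {
            mod: float(res.pxp[model_idx]) for mod, res in results.items()
        }
    return out
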