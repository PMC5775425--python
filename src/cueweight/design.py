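"""Experimental designs for the multisensory location-cueing paradigm.

A session is a sequence of blocks; within each block an auditory spatial
cue ("left"/"right") predicts the side of an upcoming visual or tactile
target with a block-constant, modality-specific probability (the *cue
predictability*).  Three canonical designs are shipped:

- ``exp1`` / ``exp2``: six 80-trial blocks mixing predictability levels
  90/70/50/30% across the two modalities (exp2 additionally pre-cues the
  target modality; the block structure is identical),
- ``exp3``: four 80-trial blocks with complementary levels, i.e.
  ``p_valid_visual + p_valid_tactile = 1`` (pairs 90/10 and 70/30).

Valid/invalid trial counts are deterministic quotas (the predictability
is a property of the block, not a sampling rate), and cue sides and
target elevations are balanced within each block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MODALITIES = ("visual", "tactile")
SIDES = ("left", "right")
ELEVATIONS = ("proximal", "distal")

EXPERIMENT_IDS = ("exp1", "exp2", "exp3")

#: Default (visual, tactile) predictability pairings for exp1/exp2.  The
#: published block-to-level assignment is only available graphically, so
#: this ordering is a documented stand-in: every level in {90,70,50,30}%
#: occurs at least once per modality and both divergence signs occur.
#: Override via ``standard_design(..., pairings=...)``.
EXP12_PAIRINGS: tuple[tuple[float, float], ...] = (
    (0.9, 0.5),
    (0.5, 0.9),
    (0.7, 0.3),
    (0.3, 0.7),
    (0.9, 0.7),
    (0.3, 0.5),
)

#: Complementary pairings for exp3 (visual, tactile).
EXP3_PAIRINGS: tuple[tuple[float, float], ...] = (
    (0.9, 0.1),
    (0.7, 0.3),
    (0.3, 0.7),
    (0.1, 0.9),
)

_SCHEMA_VERSION = "cueweight-design-v1"


@dataclass(frozen=True)
class BlockSpec:
    """One experimental block: per-modality cue predictability and size."""

    block_index: int
    p_valid_visual: float
    p_valid_tactile: float
    n_trials_per_modality: int = 40

    def __post_init__(self) -> None:
        for name in ("p_valid_visual", "p_valid_tactile"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_trials_per_modality <= 0:
            raise ValueError("n_trials_per_modality must be positive")
        for name in ("p_valid_visual", "p_valid_tactile"):
            p = getattr(self, name)
            target = p * self.n_trials_per_modality
            if abs(target - round(target)) >= 0.5 - 1e-9:
                raise ValueError(
                    f"{name}={p} with n={self.n_trials_per_modality} does not "
                    "realize an unambiguous valid/invalid count"
                )

    def p_valid(self, modality: str) -> float:
        if modality == "visual":
            return self.p_valid_visual
        if modality == "tactile":
            return self.p_valid_tactile
        raise ValueError(f"unknown modality: {modality!r}")

    def n_valid(self, modality: str) -> int:
        return int(round(self.p_valid(modality) * self.n_trials_per_modality))


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered blocks plus whether the target modality is pre-cued."""

    experiment_id: str
    blocks: tuple[BlockSpec, ...]
    modality_precue: bool

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment_id: {self.experiment_id!r}")
        n_expected = 4 if self.experiment_id == "exp3" else 6
        if len(self.blocks) != n_expected:
            raise ValueError(
                f"{self.experiment_id} requires {n_expected} blocks, "
                f"got {len(self.blocks)}"
            )
        if self.experiment_id == "exp3":
            for b in self.blocks:
                if abs(b.p_valid_visual + b.p_valid_tactile - 1.0) > 1e-9:
                    raise ValueError(
                        "exp3 blocks must have complementary predictability "
                        f"levels; block {b.block_index} has "
                        f"({b.p_valid_visual}, {b.p_valid_tactile})"
                    )

    @property
    def n_trials_total(self) -> int:
        return sum(len(MODALITIES) * b.n_trials_per_modality for b in self.blocks)


@dataclass(frozen=True)
class TrialSpec:
    """One cue-target event within a block."""

    global_index: int  # position within the block, 0-based
    modality: str
    validity: str  # "valid" | "invalid"
    cue_side: str
    target_side: str
    elevation: str

    def __post_init__(self) -> None:
        valid = self.cue_side == self.target_side
        if (self.validity == "valid") != valid:
            raise ValueError(
                "validity label inconsistent with cue/target sides: "
                f"{self.validity}, cue={self.cue_side}, target={self.target_side}"
            )


def standard_design(
    experiment_id: str,
    pairings: Sequence[tuple[float, float]] | None = None,
    n_trials_per_modality: int = 40,
) -> ExperimentDesign:
    """Return the canonical block design for one of the three experiments.

    Parameters
    ----------
    experiment_id
        One of ``"exp1"``, ``"exp2"``, ``"exp3"``.
    pairings
        Optional override of the per-block ``(p_valid_visual,
        p_valid_tactile)`` pairs; defaults to :data:`EXP12_PAIRINGS` or
        :data:`EXP3_PAIRINGS`.
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(
            f"unknown experiment_id: {experiment_id!r}; expected one of "
            f"{EXPERIMENT_IDS}"
        )
    if pairings is None:
        pairings = EXP3_PAIRINGS if experiment_id == "exp3" else EXP12_PAIRINGS
    blocks = tuple(
        BlockSpec(
            block_index=i,
            p_valid_visual=pv,
            p_valid_tactile=pt,
            n_trials_per_modality=n_trials_per_modality,
        )
        for i, (pv, pt) in enumerate(pairings)
    )
    return ExperimentDesign(
        experiment_id=experiment_id,
        blocks=blocks,
        modality_precue=experiment_id in ("exp2", "exp3"),
    )


def _balanced_labels(values: Sequence[str], n: int, rng: np.random.Generator) -> np.ndarray:
    """n labels drawn from `values` as evenly as possible, shuffled."""
    reps = np.tile(values, n // len(values) + 1)[:n]
    return rng.permutation(reps)


def randomize_trials(
    design: ExperimentDesign, seed: int
) -> list[list[TrialSpec]]:
    """Generate a seeded, balanced trial sequence for every block.

    Per block and modality, exactly ``round(p_valid * n)`` trials are
    valid; cue sides are balanced (n/2 left, n/2 right per modality) and
    target elevations are balanced.  Modalities are interleaved by a
    seeded shuffle.  The same ``(design, seed)`` always yields the same
    sequence.
    """
    rng = np.random.default_rng(seed)
    out: list[list[TrialSpec]] = []
    for block in design.blocks:
        per_modality: dict[str, list[dict]] = {}
        for modality in MODALITIES:
            n = block.n_trials_per_modality
            n_valid = block.n_valid(modality)
            validity = np.array(["valid"] * n_valid + ["invalid"] * (n - n_valid))
            validity = rng.permutation(validity)
            cue_side = _balanced_labels(SIDES, n, rng)
            elevation = _balanced_labels(ELEVATIONS, n, rng)
            per_modality[modality] = [
                {
                    "modality": modality,
                    "validity": v,
                    "cue_side": c,
                    "elevation": e,
                }
                for v, c, e in zip(validity, cue_side, elevation)
            ]
        order = rng.permutation(
            np.repeat(MODALITIES, block.n_trials_per_modality)
        )
        queues = {m: iter(per_modality[m]) for m in MODALITIES}
        trials: list[TrialSpec] = []
        for i, m in enumerate(order):
            d = next(queues[m])
            other = SIDES[1] if d["cue_side"] == SIDES[0] else SIDES[0]
            target = d["cue_side"] if d["validity"] == "valid" else other
            trials.append(
                TrialSpec(
                    global_index=i,
                    modality=d["modality"],
                    validity=d["validity"],
                    cue_side=d["cue_side"],
                    target_side=target,
                    elevation=d["elevation"],
                )
            )
        out.append(trials)
    return out


def block_factors(block: BlockSpec, modality: str) -> dict[str, float]:
    """Block-level factors (in percentage points) for one target modality.

    ``predictability_distance`` is the absolute distance of the
    modality's cue predictability from 50%; ``signed_divergence`` is the
    difference between the modality's predictability and the other
    modality's (positive when the target's modality is the more
    predictable one); ``abs_divergence`` its absolute value.
    """
    p_own = block.p_valid(modality)
    other = "tactile" if modality == "visual" else "visual"
    p_other = block.p_valid(other)
    signed = 100.0 * (p_own - p_other)
    return {
        "predictability_distance": abs(100.0 * p_own - 50.0),
        "signed_divergence": signed,
        "abs_divergence": abs(signed),
    }


def design_to_json(design: ExperimentDesign, seed: int | None = None) -> str:
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "experiment_id": design.experiment_id,
        "modality_precue": design.modality_precue,
        "blocks": [
            {
                "index": b.block_index,
                "p_valid_visual": b.p_valid_visual,
                "p_valid_tactile": b.p_valid_tactile,
                "n_trials_per_modality": b.n_trials_per_modality,
            }
            for b in design.blocks
        ],
    }
    if seed is not None:
        payload["seed"] = seed
    return json.dumps(payload, indent=2)


def design_from_json(text: str) -> ExperimentDesign:
    payload = json.loads(text)
    blocks = tuple(
        BlockSpec(
            block_index=b["index"],
            p_valid_visual=b["p_valid_visual"],
            p_valid_tactile=b["p_valid_tactile"],
            n_trials_per_modality=b.get("n_trials_per_modality", 40),
        )
        for b in payload["blocks"]
    )
    return ExperimentDesign(
        experiment_id=payload["experiment_id"],
        blocks=blocks,
        modality_precue=payload["modality_precue"],
    )
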