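"""CSV/JSON interchange: trial tables, fit results, and the tidy w-table.

Trial tables travel as plain CSV with a fixed column schema (extra
columns are tolerated); nested results (fits, model comparisons) as
JSON.  Every file written here names its schema version, either in a
leading ``#`` comment (CSV) or a ``schema_version`` key (JSON).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign, block_factors
from .response import ConstantModelFit, WeightFit

logger = logging.getLogger(__name__)

TRIALS_SCHEMA = "cueweight-trials-v1"
FITS_SCHEMA = "cueweight-fits-v1"
BMS_SCHEMA = "cueweight-bms-v1"
WTABLE_SCHEMA = "cueweight-wtable-v1"

MANDATORY_COLUMNS = (
    "subject_id",
    "experiment",
    "block",
    "trial_index",
    "modality",
    "cue_side",
    "target_side",
    "validity",
    "elevation",
    "rt_ms",
    "response",
    "correct",
)

_CATEGORICAL = {
    "modality": {"visual", "tactile"},
    "cue_side": {"left", "right"},
    "target_side": {"left", "right"},
    "validity": {"valid", "invalid"},
    "elevation": {"proximal", "distal"},
    "response": {"proximal", "distal", "none"},
}


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {TRIALS_SCHEMA}\n")
        trials.to_csv(fh, index=False)


def read_trials_csv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trial table; returns (records, rejects).

    Malformed rows (unknown category labels, negative RT) are collected
    into the rejects report with a reason column rather than silently
    dropped.  A missing mandatory column raises, naming the column.
    Empty ``rt_ms`` with ``response == "none"`` is a miss.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["response"] = df["response"].fillna("none").astype(str)
    if df["correct"].dtype == object:
        df["correct"] = df["correct"].astype(str).str.lower().isin(("true", "1"))
    df["correct"] = df["correct"].astype(bool)

    bad = np.zeros(len(df), dtype=bool)
    reasons = np.full(len(df), "", dtype=object)
    for col, allowed in _CATEGORICAL.items():
        wrong = ~df[col].astype(str).isin(allowed)
        reasons[wrong & ~bad] = f"invalid {col}"
        bad |= wrong
    neg_rt = df["rt_ms"].to_numpy() < 0
    reasons[neg_rt & ~bad] = "negative rt_ms"
    bad |= neg_rt
    # a missing RT is only legal for a miss
    orphan = df["rt_ms"].isna().to_numpy() & (df["response"] != "none").to_numpy()
    reasons[orphan & ~bad] = "missing rt_ms without miss"
    bad |= orphan

    rejects = df[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    if len(rejects):
        logger.warning("read_trials_csv: %d malformed rows rejected", len(rejects))
    return df[~bad].reset_index(drop=True), rejects


def _fit_to_dict(fit: WeightFit | ConstantModelFit) -> dict:
    d = {
        "fitting_unit": list(fit.fitting_unit),
        "log_likelihood": fit.log_likelihood,
        "log_evidence": fit.log_evidence,
        "n_trials_used": fit.n_trials_used,
        "k_params": fit.k_params,
        "flags": fit.flags,
        "converged": fit.converged,
    }
    if fit.params is not None:
        d.update(
            zeta1_valid=fit.params.zeta1_valid,
            zeta2_valid=fit.params.zeta2_valid,
            zeta1_invalid=fit.params.zeta1_invalid,
            zeta2_invalid=fit.params.zeta2_invalid,
            sigma=fit.params.sigma,
        )
    if isinstance(fit, WeightFit):
        d["model"] = "bayesian"
        d["w_hat"] = fit.w_hat
    else:
        d["model"] = "constant"
        d["p_const"] = fit.p_const
    return d


def write_fits_json(
    fits: dict[tuple, WeightFit | ConstantModelFit] | list, path: str | Path
) -> None:
    values = list(fits.values()) if isinstance(fits, dict) else list(fits)
    payload = {
        "schema_version": FITS_SCHEMA,
        "fits": [_fit_to_dict(f) for f in values],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_bms_json(results: dict, path: str | Path) -> None:
    """Serialize per-modality BMS results as {modality: {model: pxp, ...}}."""
    payload = {"schema_version": BMS_SCHEMA, "results": {}}
    for mod, res in results.items():
        names = res.model_names or tuple(
            f"model{i}" for i in range(len(res.pxp))
        )
        payload["results"][mod] = {
            "pxp": dict(zip(names, res.pxp.tolist())),
            "xp": dict(zip(names, res.xp.tolist())),
            "expected_freq": dict(zip(names, res.expected_freq.tolist())),
            "bor": res.bor,
            "dirichlet_alpha": res.dirichlet_alpha.tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def export_w_table(
    fits: dict[tuple, WeightFit],
    design: ExperimentDesign,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Tidy w-table for external group modelling (e.g. a mixed model).

    One row per (subject, block, modality) with the fitted w and the
    block factors recomputed from the design.  Units without a fit get
    a missing-value row and a warning.
    """
    if subjects is None:
        subjects = sorted({k[0] for k in fits})
    rows = []
    n_missing = 0
    for subj in subjects:
        for block in design.blocks:
            for modality in ("visual", "tactile"):
                key = (subj, block.block_index, modality)
                fit = fits.get(key)
                if fit is None or not fit.ok:
                    n_missing += 1
                factors = block_factors(block, modality)
                rows.append(
                    {
                        "subject_id": subj,
                        "experiment": design.experiment_id,
                        "block": block.block_index,
                        "modality": modality,
                        "w_hat": fit.w_hat if fit is not None and fit.ok else np.nan,
                        "predictability_distance": factors["predictability_distance"],
                        "signed_divergence": factors["signed_divergence"],
                        "abs_divergence": factors["abs_divergence"],
                    }
                )
    if n_missing:
        logger.warning("export_w_table: %d units missing a usable fit", n_missing)
    return pd.DataFrame(rows)


def write_w_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {WTABLE_SCHEMA}\n")
        table.to_csv(fh, index=False)
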