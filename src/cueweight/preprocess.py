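"""Trial exclusion rules and reaction-time to response-speed conversion.

Exclusion runs in two stages per subject.  Stage 1 drops misses (no
response), incorrect responses, and anticipations (RT < 100 ms, strict).
Stage 2 computes the mean and SD of RT over the stage-1 survivors of the
subject's whole session and drops trials deviating more than 2 SD from
that mean (single pass; the bounds are not recomputed after removal).
Surviving trials get a response speed RS = 1/RT in 1/s, the observable
modeled downstream.  Excluded trials keep their rows, labeled with the
reason, because they still drive the ideal observer's belief updates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXCLUSION_LABELS = ("kept", "incorrect", "miss", "anticipation", "outlier")

ANTICIPATION_MS = 100.0
OUTLIER_SD = 2.0


def filter_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Label every trial with an exclusion reason and add RS for kept ones.

    Expects columns ``rt_ms`` (NaN for misses), ``response``,
    ``correct``; if ``subject_id`` is present the outlier criterion is
    applied per subject.  Returns a copy with ``exclusion_reason`` and
    ``rs`` (1/s; NaN for excluded trials) columns.
    """
    out = records.copy()
    if len(out) == 0:
        out["exclusion_reason"] = pd.Series(dtype=object)
        out["rs"] = pd.Series(dtype=float)
        return out

    rt = pd.to_numeric(out["rt_ms"], errors="coerce").to_numpy(dtype=float)
    is_miss = np.isnan(rt) | (out["response"].astype(str) == "none")
    is_correct = out["correct"].astype(bool).to_numpy()
    is_anticipation = ~is_miss & (rt < ANTICIPATION_MS)

    reason = np.full(len(out), "kept", dtype=object)
    reason[~is_correct & ~is_miss] = "incorrect"
    reason[is_miss] = "miss"
    reason[is_anticipation & (reason == "kept")] = "anticipation"

    # stage 2: per-subject 2-SD outlier criterion over stage-1 survivors
    if "subject_id" in out.columns:
        groups = out.groupby("subject_id", sort=False).indices.values()
    else:
        groups = [np.arange(len(out))]
    for idx in groups:
        idx = np.asarray(idx)
        survivors = idx[reason[idx] == "kept"]
        if len(survivors) == 0:
            continue
        mu = rt[survivors].mean()
        sd = rt[survivors].std(ddof=1) if len(survivors) > 1 else 0.0
        outliers = survivors[np.abs(rt[survivors] - mu) > OUTLIER_SD * sd]
        reason[outliers] = "outlier"

    out["exclusion_reason"] = reason
    out["rs"] = np.where(reason == "kept", 1000.0 / rt, np.nan)
    n_kept = int((reason == "kept").sum())
    if n_kept == 0:
        logger.warning("filter_trials: all %d trials excluded", len(out))
    logger.info("filter_trials: kept %d of %d trials", n_kept, len(out))
    return out


def accuracy_summary(records: pd.DataFrame) -> dict:
    """Descriptive accuracy and RT summary after exclusion.

    Excluded trials of every kind (incorrect, miss, anticipation,
    outlier) count as errors, so ``pct_correct`` is the percentage of
    kept trials.  Mean RT is computed over kept trials only.
    """
    labeled = (
        records
        if "exclusion_reason" in records.columns
        else filter_trials(records)
    )
    n = len(labeled)
    kept = labeled[labeled["exclusion_reason"] == "kept"]

    def _summ(df: pd.DataFrame, total: int) -> dict:
        k = df[df["exclusion_reason"] == "kept"]
        return {
            "n_trials": total,
            "n_kept": len(k),
            "pct_correct": 100.0 * len(k) / total if total else float("nan"),
            "mean_rt_ms": float(k["rt_ms"].mean()) if len(k) else float("nan"),
            "mean_rt_defined": bool(len(k)),
        }

    summary = _summ(labeled, n)
    summary["per_modality"] = {
        m: _summ(grp, len(grp))
        for m, grp in labeled.groupby("modality", sort=False)
    } if "modality" in labeled.columns else {}
    return summary
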