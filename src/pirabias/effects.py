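"""Treatment-effect estimation: hazard ratios, risk ratios, replicate
aggregation and paired bias with bootstrap confidence intervals.

Per replicate, the effect on PIRA is a Cox hazard ratio for time to first
PIRA (arm as the sole covariate, Efron tie handling — integer-day event times
are heavily tied) or the ratio of per-arm PIRA proportions. Across
replicates, ratio measures are aggregated as the geometric mean (arithmetic
mean available behind a flag) and confidence intervals come from a
percentile bootstrap over replicates. Bias is the difference between the
aggregated estimated and true effects, with a paired bootstrap (the same
replicate resample enters both aggregates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .model import DetectedEvent

__all__ = [
    "SurvivalRecord",
    "EffectEstimate",
    "EstimationError",
    "time_to_first_pira",
    "survival_table",
    "estimate_hr",
    "estimate_rr",
    "aggregate_replicates",
    "paired_bias",
]

log = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """A replicate-level fit failed (degenerate data, non-convergence)."""


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    arm: str
    time_days: int
    event: bool


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio effect measure with CI. ``n_replicates`` is 1 for a
    single-replicate fit, else the number aggregated."""

    measure: str  # "HR" or "RR"
    point: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_replicates: int = 1


def time_to_first_pira(
    patient_id: str,
    arm: str,
    events: Sequence[DetectedEvent],
    followup_end: int,
) -> SurvivalRecord:
    """Time of the first PIRA onset; censored at follow-up end otherwise."""
    for e in events:
        if e.kind == "worsening" and e.classification == "PIRA":
            return SurvivalRecord(patient_id, arm, int(e.onset_day), True)
    return SurvivalRecord(patient_id, arm, int(followup_end), False)


def survival_table(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    recs = list(records)
    return pd.DataFrame(
        {
            "time": [r.time_days for r in recs],
            "event": [r.event for r in recs],
            "arm": [1 if r.arm == "treated" else 0 for r in recs],
        }
    )


def estimate_hr(records: Iterable[SurvivalRecord] | pd.DataFrame) -> EffectEstimate:
    """Cox proportional-hazards fit with arm as the sole covariate.

    Raises :class:`EstimationError` when either arm lacks records, no events
    occurred, or the partial likelihood is degenerate (monotone likelihood,
    e.g. all events in one arm with the other fully censored).
    """
    df = records if isinstance(records, pd.DataFrame) else survival_table(records)
    if df.empty or df["arm"].nunique() < 2:
        raise EstimationError("both arms must contribute records")
    if not df["event"].any():
        raise EstimationError("no events in either arm")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-9})
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(f"Cox fit failed: {exc}") from exc
    beta = float(cph.params_.loc["arm"])
    lo, hi = cph.confidence_intervals_.loc["arm"]
    if not np.isfinite(beta) or abs(beta) > 10:
        raise EstimationError("monotone likelihood, hazard ratio diverges")
    return EffectEstimate("HR", float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)))


def estimate_rr(
    treated_events: int, treated_n: int, control_events: int, control_n: int
) -> EffectEstimate:
    """Risk ratio as the ratio of per-arm event proportions (no CI at the
    replicate level; CIs come from replicate aggregation)."""
    if treated_n == 0 or control_n == 0:
        raise EstimationError("both arms must be non-empty")
    p_control = control_events / control_n
    if p_control == 0:
        raise EstimationError("control proportion is zero, risk ratio undefined")
    point = (treated_events / treated_n) / p_control
    return EffectEstimate("RR", point)


def aggregate_replicates(
    values: Sequence[float],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    measure: str = "HR",
    scale: str = "log",
) -> EffectEstimate:
    """Aggregate per-replicate ratio estimates with a percentile bootstrap CI.

    ``scale="log"`` (default) aggregates as the geometric mean, appropriate
    for ratio measures; ``scale="natural"`` uses the arithmetic mean. Non-
    finite or non-positive replicate values are excluded with a logged count.
    """
    vals = np.asarray(values, dtype=np.float64)
    keep = np.isfinite(vals) & (vals > 0 if scale == "log" else np.isfinite(vals))
    if keep.sum() < vals.size:
        log.warning("aggregate_replicates: excluded %d invalid replicate(s)", vals.size - keep.sum())
    vals = vals[keep]
    if vals.size < 2:
        raise EstimationError("need at least two valid replicate estimates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def agg(x: np.ndarray) -> float:
        return float(np.exp(np.mean(np.log(x))) if scale == "log" else np.mean(x))

    point = agg(vals)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    boot = vals[idx]
    if scale == "log":
        boots = np.exp(np.mean(np.log(boot), axis=1))
    else:
        boots = np.mean(boot, axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectEstimate(measure, point, float(lo), float(hi), n_replicates=int(vals.size))


def paired_bias(
    estimated: Sequence[float],
    true: Sequence[float],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    scale: str = "log",
) -> tuple[float, float, float]:
    """Bias of the aggregated estimate versus the aggregated truth.

    bias = agg(estimated) - agg(true), with a paired percentile bootstrap:
    each bootstrap resample of replicate indices is applied to both series,
    so shared Monte-Carlo noise cancels. Replicates invalid in either series
    are dropped pairwise. Returns (bias, ci_low, ci_high).
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(true, dtype=np.float64)
    if est.size != tru.size:
        raise ValueError("estimated and true series must be paired per replicate")
    keep = np.isfinite(est) & np.isfinite(tru)
    if scale == "log":
        keep &= (est > 0) & (tru > 0)
    if keep.sum() < est.size:
        log.warning("paired_bias: excluded %d invalid pair(s)", est.size - keep.sum())
    est, tru = est[keep], tru[keep]
    if est.size < 2:
        raise EstimationError("need at least two valid replicate pairs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def agg(x: np.ndarray, axis=None) -> np.ndarray:
        return np.exp(np.mean(np.log(x), axis=axis)) if scale == "log" else np.mean(x, axis=axis)

    bias = float(agg(est) - agg(tru))
    idx = rng.integers(0, est.size, size=(n_boot, est.size))
    boots = agg(est[idx], axis=1) - agg(tru[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return bias, float(lo), float(hi)
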