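"""Confirmed disability-accrual (CDA) event detection.

A worsening candidate at visit *v* requires an EDSS increase versus the
current reference of at least :func:`pirabias.model.threshold` (>=1.0 from a
reference <=5.5, >=0.5 above). The candidate is confirmed by the first
eligible visit *c* at least ``confirmation_days`` (84 d) later such that every
visit strictly between *v* and *c*, and *c* itself, sustains the change
relative to the reference. A visit occurring within
``confirmation_relapse_exclusion_days`` (30 d, closed window) after any
relapse onset cannot serve as confirmation — but it still must sustain the
change. Improvements use the same magnitude rule mirrored; they exist to
drive the roving baseline.

Baseline schemes
----------------
roving
    The reference resets to the confirmation visit of every confirmed
    worsening or improvement event; scanning resumes at that visit.
relapse_rebaseline
    Additionally, after each relapse the reference resets at the first visit
    >=30 days after the onset whose EDSS is not below the *original* (day-0)
    baseline. Event-driven resets still apply on top; a relapse reset whose
    visit was overtaken by an event confirmation is superseded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .model import AnalysisConfig, DetectedEvent, PatientTrajectory, Relapse, RicTrajectory, threshold

__all__ = [
    "BaselineState",
    "detect_events",
    "apply_roving_baseline",
    "apply_relapse_rebaseline",
    "confirmation_eligible",
]

Trajectory = Union[PatientTrajectory, RicTrajectory]


@dataclass(frozen=True)
class BaselineState:
    """Current reference visit against which changes are measured."""

    reference_day: int
    reference_value: float


def apply_roving_baseline(state: BaselineState, event: DetectedEvent) -> BaselineState:
    """Reset the reference to the confirmation visit of a confirmed event."""
    return BaselineState(event.confirmation_day, event.confirmation_value)


def apply_relapse_rebaseline(
    traj: Trajectory, state: BaselineState, relapse: Relapse, min_gap_days: int = 30
) -> BaselineState:
    """Reference reset after a relapse (closed >=30-day gap).

    Returns the state anchored at the first visit at least ``min_gap_days``
    after the relapse onset whose EDSS is not lower than the original day-0
    baseline; if no visit qualifies the state is unchanged.
    """
    original = traj.scores[0]
    for d, e in zip(traj.days, traj.scores):
        if d - relapse.onset_day >= min_gap_days and e >= original:
            return BaselineState(int(d), float(e))
    return state


def confirmation_eligible(traj: Trajectory, config: AnalysisConfig) -> np.ndarray:
    """Boolean mask: visit may serve as a confirmation visit.

    A visit is barred when it falls within the closed window
    ``[onset, onset + exclusion]`` after any relapse onset (a visit on the
    relapse day itself is excluded).
    """
    days = traj.days
    rel = traj.relapse_days
    if rel.size == 0:
        return np.ones(days.size, dtype=bool)
    gaps = days[:, None] - rel[None, :]
    return ~np.any((gaps >= 0) & (gaps <= config.confirmation_relapse_exclusion_days), axis=1)


def detect_events(traj: Trajectory, config: AnalysisConfig | None = None) -> list[DetectedEvent]:
    """Scan a trajectory left to right and return confirmed events in onset order.

    Events are non-overlapping: after a confirmation the scan resumes at the
    confirmation visit, which becomes the new reference. Classification
    fields are left at "n/a"; see :mod:`pirabias.classify`.
    """
    if config is None:
        config = AnalysisConfig()
    days = traj.days
    scores = traj.scores
    n = days.size
    eligible = confirmation_eligible(traj, config)
    conf_gap = config.confirmation_days

    rebase_at: dict[int, int] = {}
    if config.baseline_scheme == "relapse_rebaseline":
        original = scores[0]
        for onset in traj.relapse_days:
            for j in range(n):
                if days[j] - onset >= 30 and scores[j] >= original:
                    rebase_at[j] = j  # reset anchored at visit j
                    break

    events: list[DetectedEvent] = []
    ref_day, ref_val = int(days[0]), float(scores[0])
    i = 1
    while i < n:
        if i in rebase_at:
            ref_day, ref_val = int(days[i]), float(scores[i])
        thr = threshold(ref_val)
        delta = scores[i] - ref_val
        kind = None
        if delta >= thr:
            kind = "worsening"
        elif -delta >= thr:
            kind = "improvement"
        if kind is not None:
            sign = 1.0 if kind == "worsening" else -1.0
            conf = -1
            for j in range(i + 1, n):
                if sign * (scores[j] - ref_val) < thr:
                    break  # change not sustained; candidate dead
                if days[j] - days[i] >= conf_gap and eligible[j]:
                    conf = j
                    break
            if conf >= 0:
                events.append(
                    DetectedEvent(
                        kind=kind,
                        onset_day=int(days[i]),
                        onset_value=float(scores[i]),
                        reference_day=ref_day,
                        reference_value=ref_val,
                        confirmation_day=int(days[conf]),
                        confirmation_value=float(scores[conf]),
                    )
                )
                ref_day, ref_val = int(days[conf]), float(scores[conf])
                # stale relapse resets at skipped visits are superseded
                for k in list(rebase_at):
                    if k <= conf:
                        del rebase_at[k]
                i = conf + 1
                continue
        i += 1
    return events
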