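"""Classification of confirmed worsening events as PIRA / RAW / undefined.

RAW (relapse-associated worsening): a confirmed worsening whose onset falls
within the closed 90-day window after a relapse onset. PIRA definitions
require relapse-free intervals anchored at the reference, event and
confirmation visits; all intervals are closed:

========== ================================================================
standard1  [reference, confirmation]
standard2  [reference, event + 30] and [confirmation - 30, confirmation + 30]
standard3  [event - 90, event + 30] and [confirmation - 90, confirmation + 30]
non_raw    [event - 90, event]  (exact complement of the RAW predicate)
========== ================================================================

A worsening that fails its definition's intervals is RAW when the RAW
predicate holds, otherwise *undefined*. Under ``non_raw`` no event can be
undefined, so #PIRA + #RAW equals the total CDA count exactly.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

from .model import AnalysisConfig, DetectedEvent, PatientTrajectory, RicTrajectory, ValidationError

__all__ = [
    "definition_intervals",
    "classify_raw",
    "classify_pira",
    "classify_raw_subtype",
    "classify_events",
]

Trajectory = Union[PatientTrajectory, RicTrajectory]


def definition_intervals(
    event: DetectedEvent, definition: str, config: AnalysisConfig
) -> list[tuple[int, int]]:
    """Closed day intervals that must be relapse-free for PIRA."""
    e, r, c = event.onset_day, event.reference_day, event.confirmation_day
    w = config.raw_window_days
    if definition == "standard1":
        return [(r, c)]
    if definition == "standard2":
        return [(r, e + 30), (c - 30, c + 30)]
    if definition == "standard3":
        return [(e - w, e + 30), (c - w, c + 30)]
    if definition == "non_raw":
        return [(e - w, e)]
    raise ValidationError(f"unknown PIRA definition {definition!r}")


def classify_raw(
    event: DetectedEvent, relapse_days: Sequence[int] | np.ndarray, config: AnalysisConfig
) -> bool:
    """True iff a relapse onset precedes (or coincides with) the event onset
    by at most ``raw_window_days``."""
    e = event.onset_day
    return any(0 <= e - int(r) <= config.raw_window_days for r in relapse_days)


def classify_pira(
    event: DetectedEvent,
    relapse_days: Sequence[int] | np.ndarray,
    definition: str,
    config: AnalysisConfig | None = None,
) -> str:
    """Classify a confirmed worsening as "PIRA", "RAW" or "undefined"."""
    if config is None:
        config = AnalysisConfig()
    intervals = definition_intervals(event, definition, config)
    clean = all(
        not any(lo <= int(r) <= hi for r in relapse_days) for lo, hi in intervals
    )
    if clean:
        return "PIRA"
    return "RAW" if classify_raw(event, relapse_days, config) else "undefined"


def classify_raw_subtype(event: DetectedEvent, traj: Trajectory) -> str:
    """"transient" if the score later returns to (or below) the reference
    level, "sustained" otherwise (including when no later visit exists)."""
    later = traj.scores[traj.days > event.onset_day]
    return "transient" if np.any(later <= event.reference_value) else "sustained"


def classify_events(
    traj: Trajectory,
    events: Sequence[DetectedEvent],
    definition: str | None = None,
    config: AnalysisConfig | None = None,
) -> list[DetectedEvent]:
    """Return events with classification / raw_subtype filled on worsenings.

    Improvements keep classification "n/a" (they only drive the roving
    baseline).
    """
    if config is None:
        config = AnalysisConfig()
    if definition is None:
        definition = config.pira_definition
    out: list[DetectedEvent] = []
    rel = traj.relapse_days
    from dataclasses import replace

    for e in events:
        if e.kind != "worsening":
            out.append(e)
            continue
        cls = classify_pira(e, rel, definition, config)
        sub = classify_raw_subtype(e, traj) if cls == "RAW" else "n/a"
        out.append(replace(e, classification=cls, raw_subtype=sub))
    return out
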