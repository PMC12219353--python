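"""Relapse-independent component (RIC) trajectory decomposition.

Instead of classifying events post hoc, this approach subtracts the magnitude
of relapse-associated changes from the trajectory and detects confirmed
worsening on the residual, so every resulting event is PIRA by construction.

For each relapse (in onset order, each computed on the already-adjusted
values):

* ``pre``  — EDSS at the last visit before the onset (the day-0 value if the
  relapse precedes every later visit);
* ``delta`` — acute relapse-associated increment: the excess over ``pre`` of
  the maximum EDSS within the closed influence window
  ``[onset, onset + raw_window_days]`` (0 if no rise);
* ``rho`` — sustained residual: the excess over ``pre`` of the *minimum* EDSS
  after the window, capped at ``delta`` (the minimum avoids attributing later
  relapse-independent progression to the relapse).

Visits inside the window lose the transient excess ``min(delta, excess over
pre)``; visits after the window lose ``rho``. Adjusted scores may leave the
half-point grid and are deliberately not re-rounded — re-rounding would
reintroduce relapse artefacts.
"""

from __future__ import annotations

import numpy as np

from .model import AnalysisConfig, DetectedEvent, PatientTrajectory, RicTrajectory
from .events import detect_events

__all__ = ["decompose", "detect_pira_ric"]


def decompose(traj: PatientTrajectory, config: AnalysisConfig | None = None) -> RicTrajectory:
    """Subtract relapse-associated changes, returning the residual trajectory.

    Identity on relapse-free trajectories. Overlapping relapse influence
    windows are handled sequentially, each relapse seeing the adjustment made
    by the previous ones.
    """
    if config is None:
        config = AnalysisConfig()
    days = traj.days
    adj = traj.scores.astype(np.float64).copy()
    window = config.raw_window_days
    for onset in traj.relapse_days:
        before = days < onset
        pre = adj[before][-1] if np.any(before) else adj[0]
        in_window = (days >= onset) & (days <= onset + window)
        after = days > onset + window
        if not np.any(in_window) and not np.any(after):
            continue
        delta = max(0.0, float(np.max(adj[in_window])) - pre) if np.any(in_window) else 0.0
        if np.any(after):
            rho = min(delta, max(0.0, float(np.min(adj[after])) - pre))
        else:
            rho = 0.0
        transient_idx = (days > onset) & (days <= onset + window)
        excess = np.maximum(adj[transient_idx] - pre, 0.0)
        adj[transient_idx] -= np.minimum(delta, excess)
        adj[after] -= rho
    return RicTrajectory(
        patient_id=traj.patient_id,
        arm=traj.arm,
        days=days,
        scores=adj,
        relapse_days=traj.relapse_days,
        followup_end=traj.followup_end,
    )


def detect_pira_ric(
    traj: PatientTrajectory, config: AnalysisConfig | None = None
) -> list[DetectedEvent]:
    """Detect confirmed events on the RIC trajectory (roving baseline).

    Thresholds are evaluated on the raw adjusted values; the relapse-based
    confirmation-visit exclusion still applies. All worsening events are
    labelled PIRA by construction; improvements keep "n/a".
    """
    if config is None:
        config = AnalysisConfig()
    from dataclasses import replace

    ric = decompose(traj, config)
    events = detect_events(ric, config)
    return [
        replace(e, classification="PIRA") if e.kind == "worsening" else e
        for e in events
    ]
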