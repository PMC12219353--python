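"""CSV readers/writers for visit, relapse and event tables.

Formats (comma-separated, UTF-8, header row mandatory):

* visits:   ``patient_id,day,edss``
* relapses: ``patient_id,onset_day``
* events:   ``patient_id,kind,onset_day,reference_day,reference_value,
  onset_value,confirmation_day,classification,raw_subtype``

Validation problems are aggregated and reported together with 1-based data
row numbers, so a malformed file yields one error listing every bad row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DetectedEvent, PatientTrajectory, ValidationError, is_half_point

__all__ = ["read_trial", "write_trial", "write_events", "read_events"]

VISIT_COLUMNS = ("patient_id", "day", "edss")
RELAPSE_COLUMNS = ("patient_id", "onset_day")
EVENT_COLUMNS = (
    "patient_id",
    "kind",
    "onset_day",
    "reference_day",
    "reference_value",
    "onset_value",
    "confirmation_day",
    "confirmation_value",
    "classification",
    "raw_subtype",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def read_trial(
    visits_csv: str | Path,
    relapses_csv: str | Path | None = None,
    arms: Mapping[str, str] | None = None,
) -> list[PatientTrajectory]:
    """Read a trial as one :class:`PatientTrajectory` per patient.

    Patients absent from the relapse table get an empty relapse list. The
    follow-up end is taken as the later of the last visit and last relapse.
    ``arms`` optionally maps patient_id to "control"/"treated" (default
    "control", since arm labels are not part of the CSV schema).
    """
    visits = pd.read_csv(visits_csv)
    _require_columns(visits, VISIT_COLUMNS, visits_csv)
    if relapses_csv is not None:
        relapses = pd.read_csv(relapses_csv)
        _require_columns(relapses, RELAPSE_COLUMNS, relapses_csv)
    else:
        relapses = pd.DataFrame({"patient_id": [], "onset_day": []})

    problems: list[str] = []
    for row, (day, edss) in enumerate(zip(visits["day"], visits["edss"]), start=1):
        if not float(day).is_integer() or day < 0:
            problems.append(f"visits row {row}: day {day} is not a non-negative integer")
        if not (0.0 <= edss <= 10.0) or not is_half_point(float(edss)):
            problems.append(f"visits row {row}: EDSS {edss} not on the half-point grid in [0, 10]")
    dup = visits.duplicated(subset=["patient_id", "day"])
    for row in (np.flatnonzero(dup.to_numpy()) + 1):
        problems.append(f"visits row {row}: duplicate (patient_id, day) assessment")
    for row, onset in enumerate(relapses["onset_day"], start=1):
        if not float(onset).is_integer() or onset < 0:
            problems.append(f"relapses row {row}: onset_day {onset} is not a non-negative integer")
    if problems:
        raise ValidationError("; ".join(problems))

    rel_by_patient = {
        pid: np.sort(grp["onset_day"].to_numpy(dtype=np.int64))
        for pid, grp in relapses.groupby("patient_id", sort=False)
    }
    out: list[PatientTrajectory] = []
    for pid, grp in visits.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=np.int64)
        scores = grp["edss"].to_numpy(dtype=np.float64)
        rel = rel_by_patient.get(pid, np.empty(0, dtype=np.int64))
        followup = int(max(days[-1], rel[-1] if rel.size else 0))
        arm = (arms or {}).get(str(pid), "control")
        out.append(PatientTrajectory(str(pid), arm, days, scores, rel, followup))
    return out


def write_trial(
    trajectories: Iterable[PatientTrajectory],
    visits_csv: str | Path,
    relapses_csv: str | Path,
) -> None:
    """Write trajectories back to the visits/relapses CSV pair."""
    vrows, rrows = [], []
    for t in trajectories:
        for d, e in zip(t.days, t.scores):
            vrows.append((t.patient_id, int(d), float(e)))
        for d in t.relapse_days:
            rrows.append((t.patient_id, int(d)))
    pd.DataFrame(vrows, columns=list(VISIT_COLUMNS)).to_csv(visits_csv, index=False)
    pd.DataFrame(rrows, columns=list(RELAPSE_COLUMNS)).to_csv(relapses_csv, index=False)


def write_events(
    events_by_patient: Mapping[str, Sequence[DetectedEvent]],
    path: str | Path,
) -> None:
    rows = []
    for pid, events in events_by_patient.items():
        for e in events:
            rows.append(
                (pid, e.kind, e.onset_day, e.reference_day, e.reference_value,
                 e.onset_value, e.confirmation_day, e.confirmation_value,
                 e.classification, e.raw_subtype)
            )
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, path)
    return df
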