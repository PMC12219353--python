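"""Core data model for EDSS disability trajectories.

The package works on long-format visit data: each patient contributes an
ordered sequence of (study day, EDSS) assessments, day 0 being randomisation,
plus a list of relapse-onset days. EDSS (Expanded Disability Status Scale) is
an ordinal score on the half-point grid 0.0-10.0. Trajectories are stored
array-backed for speed; :class:`Visit` / :class:`Relapse` views are
materialised on demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "Visit",
    "Relapse",
    "PatientTrajectory",
    "RicTrajectory",
    "DetectedEvent",
    "AnalysisConfig",
    "ValidationError",
    "threshold",
    "is_half_point",
]

Arm = Literal["control", "treated"]

#: Definitions that classify confirmed worsening events post hoc by
#: relapse-free intervals; "ric" (trajectory decomposition) is handled
#: separately, see :mod:`pirabias.ric`.
INTERVAL_DEFINITIONS = ("standard1", "standard2", "standard3", "non_raw")


class ValidationError(ValueError):
    """Raised when input data violate the EDSS/trajectory invariants."""


def is_half_point(x: float) -> bool:
    """True if ``x`` lies on the EDSS half-point grid."""
    return abs(2.0 * x - round(2.0 * x)) < 1e-9


def threshold(reference_value: float) -> float:
    """Minimal EDSS increase that counts as disability worsening.

    The conventional step is >=1.0 points from a reference EDSS <=5.5 and
    >=0.5 points above 5.5 (where the scale compresses). The same magnitude
    rule, mirrored, is applied to improvements.
    """
    return 1.0 if reference_value <= 5.5 else 0.5


@dataclass(frozen=True)
class Visit:
    """A single EDSS assessment at an integer study day."""

    day: int
    edss: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"visit day must be >= 0, got {self.day}")
        if not (0.0 <= self.edss <= 10.0):
            raise ValidationError(f"EDSS {self.edss} outside [0, 10]")
        if not is_half_point(self.edss):
            raise ValidationError(f"EDSS {self.edss} not on the half-point grid")


@dataclass(frozen=True)
class Relapse:
    """A relapse with integer onset day (pre-baseline relapses out of scope)."""

    onset_day: int

    def __post_init__(self) -> None:
        if self.onset_day < 0:
            raise ValidationError(f"relapse onset must be >= 0, got {self.onset_day}")


@dataclass
class PatientTrajectory:
    """One subject's visit sequence, relapse history and follow-up window.

    Parameters
    ----------
    patient_id : str
    arm : {"control", "treated"}
    days, scores : ndarray
        Visit days (strictly increasing, first at day 0) and EDSS values on
        the half-point grid.
    relapse_days : ndarray
        Sorted relapse-onset days, all within follow-up.
    followup_end : int
        Last study day; censoring time for patients without events.
    """

    patient_id: str
    arm: Arm
    days: np.ndarray
    scores: np.ndarray
    relapse_days: np.ndarray
    followup_end: int
    validate: bool = True

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.relapse_days = np.asarray(self.relapse_days, dtype=np.int64)
        if self.validate:
            self._check()

    def _check(self) -> None:
        if self.days.size == 0:
            raise ValidationError(f"{self.patient_id}: at least one visit required")
        if self.days.size != self.scores.size:
            raise ValidationError(f"{self.patient_id}: days/scores length mismatch")
        if self.days[0] != 0:
            raise ValidationError(f"{self.patient_id}: first visit must be at day 0")
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(f"{self.patient_id}: visit days must be strictly increasing")
        if np.any(self.scores < 0.0) or np.any(self.scores > 10.0):
            raise ValidationError(f"{self.patient_id}: EDSS outside [0, 10]")
        twice = 2.0 * self.scores
        if np.any(np.abs(twice - np.round(twice)) > 1e-9):
            raise ValidationError(f"{self.patient_id}: EDSS off the half-point grid")
        if np.any(self.relapse_days < 0):
            raise ValidationError(f"{self.patient_id}: relapse onset before day 0")
        if np.any(np.diff(self.relapse_days) < 0):
            raise ValidationError(f"{self.patient_id}: relapses not sorted")
        if self.relapse_days.size and self.relapse_days[-1] > self.followup_end:
            raise ValidationError(f"{self.patient_id}: relapse after follow-up end")

    @classmethod
    def from_visits(
        cls,
        patient_id: str,
        visits: Iterable[tuple[int, float]],
        relapses: Iterable[int] = (),
        arm: Arm = "control",
        followup_end: int | None = None,
    ) -> "PatientTrajectory":
        """Build a validated trajectory from (day, edss) pairs."""
        pairs = list(visits)
        days = np.array([d for d, _ in pairs], dtype=np.int64)
        scores = np.array([e for _, e in pairs], dtype=np.float64)
        rel = np.sort(np.asarray(list(relapses), dtype=np.int64))
        if followup_end is None:
            followup_end = int(max(days[-1] if days.size else 0, rel[-1] if rel.size else 0))
        return cls(patient_id, arm, days, scores, rel, followup_end)

    @property
    def visits(self) -> tuple[Visit, ...]:
        return tuple(Visit(int(d), float(e)) for d, e in zip(self.days, self.scores))

    @property
    def relapses(self) -> tuple[Relapse, ...]:
        return tuple(Relapse(int(d)) for d in self.relapse_days)

    @property
    def baseline(self) -> float:
        """EDSS at the day-0 visit (the original study baseline)."""
        return float(self.scores[0])


@dataclass
class RicTrajectory:
    """Relapse-independent component of a trajectory.

    Same visit days as the source; adjusted scores may leave the half-point
    grid after subtraction of relapse-associated changes. Relapse days are
    retained because the confirmation-visit exclusion still applies when
    detecting events on the residual trajectory.
    """

    patient_id: str
    arm: Arm
    days: np.ndarray
    scores: np.ndarray
    relapse_days: np.ndarray
    followup_end: int

    @property
    def baseline(self) -> float:
        return float(self.scores[0])


@dataclass(frozen=True)
class DetectedEvent:
    """A confirmed disability worsening or improvement.

    ``onset_day`` is the first visit meeting the change threshold versus the
    reference; ``confirmation_day`` is the first eligible visit >=84 days
    later sustaining it. ``classification`` applies to worsening events only
    (PIRA / RAW / undefined); RAW events are further ``transient`` if the
    score later returns to the reference level, else ``sustained``.
    """

    kind: Literal["worsening", "improvement"]
    onset_day: int
    onset_value: float
    reference_day: int
    reference_value: float
    confirmation_day: int
    confirmation_value: float
    classification: Literal["PIRA", "RAW", "undefined", "n/a"] = "n/a"
    raw_subtype: Literal["transient", "sustained", "n/a"] = "n/a"


@dataclass(frozen=True)
class AnalysisConfig:
    """Window constants and scheme choices for event detection/classification.

    confirmation_days
        Minimal onset-to-confirmation separation (84 d = 12 weeks).
    confirmation_relapse_exclusion_days
        A visit within this many days after a relapse onset cannot serve as a
        confirmation visit (closed window, 30 d).
    raw_window_days
        A worsening with onset within this many days after a relapse onset is
        relapse-associated (RAW, 90 d).
    baseline_scheme
        "roving" resets the reference at the confirmation of every event;
        "relapse_rebaseline" additionally resets it at the first visit >=30 d
        after each relapse with EDSS not below the original baseline.
    pira_definition
        Which relapse-free-interval rule classifies worsenings as PIRA.
    """

    confirmation_days: int = 84
    confirmation_relapse_exclusion_days: int = 30
    raw_window_days: int = 90
    baseline_scheme: Literal["roving", "relapse_rebaseline"] = "roving"
    pira_definition: Literal["standard1", "standard2", "standard3", "non_raw"] = "standard1"

    def __post_init__(self) -> None:
        for name in ("confirmation_days", "confirmation_relapse_exclusion_days", "raw_window_days"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.baseline_scheme not in ("roving", "relapse_rebaseline"):
            raise ValidationError(f"unknown baseline scheme {self.baseline_scheme!r}")
        if self.pira_definition not in INTERVAL_DEFINITIONS:
            raise ValidationError(f"unknown PIRA definition {self.pira_definition!r}")
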