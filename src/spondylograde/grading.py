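"""Meyerding slip-ratio computation and grading.

The Meyerding scheme quantifies anterior vertebral slip as the displacement of
the upper vertebra relative to the superior endplate of the vertebra below,
expressed as a fraction of that endplate's sagittal diameter and binned into
quartiles: grade I up to 1/4, II up to 2/4, III up to 3/4, IV beyond. A study
is positive for spondylolisthesis when any level reaches grade I or higher.

The measurement construction: project the upper vertebra's lower-posterior
corner onto the line through the lower vertebra's superior endplate; the slip
distance is the (anterior-positive) offset of that projection from the lower
endplate's posterior corner. Ratios are dimensionless, so the result is
invariant to translation, rotation and uniform scaling of the radiograph.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import LandmarkSet, VertebraCorners

#: Default slip ratio at or below which a level is called Normal rather than
#: grade I. Meyerding defines no grade 0; any positive measurement noise would
#: otherwise grade a healthy level as I.
DEFAULT_NORMAL_EPSILON = 0.05

LEVEL_PAIRS = [("L1", "L2"), ("L2", "L3"), ("L3", "L4"), ("L4", "L5"), ("L5", "S1")]


class Grade(enum.IntEnum):
    """Meyerding grade; ordering reflects severity."""

    NORMAL = 0
    I = 1
    II = 2
    III = 3
    IV = 4

    def __str__(self) -> str:
        return "Normal" if self is Grade.NORMAL else self.name


class DegenerateEndplateError(ValueError):
    """Lower endplate corners coincide; no slip direction is defined."""


class NotAssessableError(ValueError):
    """No adjacent vertebra pair has complete landmarks."""


@dataclass
class SlipMeasurement:
    """Slip measurement at one intervertebral level (e.g. ``"L4/L5"``)."""

    level: str
    slip_distance_px: float
    endplate_length_px: float
    slip_ratio: float
    grade: Grade
    retrolisthesis: bool = False

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "slip_distance_px": self.slip_distance_px,
            "endplate_length_px": self.endplate_length_px,
            "slip_ratio": self.slip_ratio,
            "grade": str(self.grade),
            "retrolisthesis": self.retrolisthesis,
        }


@dataclass
class StudyAssessment:
    """Per-level measurements plus the study-level diagnosis."""

    measurements: list[SlipMeasurement]
    missing_pairs: list[str] = field(default_factory=list)

    @property
    def positive(self) -> bool:
        return any(m.grade >= Grade.I for m in self.measurements)

    @property
    def max_grade(self) -> Grade:
        return max((m.grade for m in self.measurements), default=Grade.NORMAL)

    @property
    def max_grade_level(self) -> str | None:
        worst = None
        for m in self.measurements:
            if worst is None or m.grade > worst.grade:
                worst = m
        return None if worst is None or worst.grade == Grade.NORMAL else worst.level

    def to_dict(self) -> dict:
        return {
            "measurements": [m.to_dict() for m in self.measurements],
            "missing_pairs": self.missing_pairs,
            "diagnosis_positive": self.positive,
            "max_grade": str(self.max_grade),
            "max_grade_level": self.max_grade_level,
        }


def slip_ratio(upper: VertebraCorners, lower_upper_anterior, lower_upper_posterior,
               normal_epsilon: float = DEFAULT_NORMAL_EPSILON,
               level: str = "") -> SlipMeasurement:
    """Measure anterior slip of `upper` over the endplate below it.

    Parameters
    ----------
    upper
        Corner landmarks of the upper vertebra; only its ``lower_posterior``
        corner enters the measurement.
    lower_upper_anterior, lower_upper_posterior
        The two superior-endplate corners of the vertebra (or sacrum) below,
        as (x, y) pairs.
    """
    ant = np.asarray(lower_upper_anterior, dtype=float)
    post = np.asarray(lower_upper_posterior, dtype=float)
    length = float(np.linalg.norm(ant - post))
    if length <= 0.0 or not math.isfinite(length):
        raise DegenerateEndplateError(
            f"coincident superior-endplate corners at {level or 'level'}")
    u = (ant - post) / length
    ref = np.asarray(upper.lower_posterior, dtype=float)
    distance = float(np.dot(ref - post, u))
    retro = distance < 0.0
    distance = max(0.0, distance)
    ratio = distance / length
    return SlipMeasurement(
        level=level,
        slip_distance_px=distance,
        endplate_length_px=length,
        slip_ratio=ratio,
        grade=grade_from_ratio(ratio, normal_epsilon),
        retrolisthesis=retro,
    )


def grade_from_ratio(ratio: float, normal_epsilon: float = DEFAULT_NORMAL_EPSILON) -> Grade:
    """Map a slip ratio to a Meyerding grade.

    Boundaries are inclusive on the lower grade ("does not exceed 1/4" is
    grade I), i.e. grade I covers (normal_epsilon, 1/4], II covers (1/4, 2/4],
    III (2/4, 3/4], IV beyond 3/4.
    """
    if not math.isfinite(ratio) or ratio < 0:
        raise ValueError(f"slip ratio must be finite and non-negative, got {ratio}")
    if ratio <= normal_epsilon:
        return Grade.NORMAL
    if ratio <= 0.25:
        return Grade.I
    if ratio <= 0.50:
        return Grade.II
    if ratio <= 0.75:
        return Grade.III
    return Grade.IV


def assess_study(landmarks: LandmarkSet,
                 normal_epsilon: float = DEFAULT_NORMAL_EPSILON) -> StudyAssessment:
    """Grade every assessable adjacent level and form the overall diagnosis.

    A pair is assessable when the upper vertebra's lower-posterior corner and
    both superior-endplate corners of the structure below are available.
    Raises :class:`NotAssessableError` if no pair can be measured.
    """
    measurements: list[SlipMeasurement] = []
    missing: list[str] = []
    for up_id, lo_id in LEVEL_PAIRS:
        pair = f"{up_id}/{lo_id}"
        upper = landmarks.get(up_id)
        lower = landmarks.get(lo_id)
        if upper is None or lower is None:
            missing.append(pair)
            continue
        measurements.append(
            slip_ratio(upper, lower.upper_anterior, lower.upper_posterior,
                       normal_epsilon=normal_epsilon, level=pair))
    if not measurements:
        raise NotAssessableError(
            f"no adjacent vertebra pair has complete landmarks (missing: {missing})")
    return StudyAssessment(measurements=measurements, missing_pairs=missing)
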