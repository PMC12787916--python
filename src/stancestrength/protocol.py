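"""The six-direction standing strength protocol.

A participant stands on the platform and produces maximal isometric
efforts in six directions — two in the frontal plane (adduction A,
abduction B, measured on the mediolateral axis Fx with both feet level)
and four in the sagittal plane (forward push / backward pull with the
right or left leg forward: D1, D2, K1, K2, measured on the
anteroposterior axis Fy in a staggered stance).  Each direction is
attempted three times with one minute of rest; the best windowed-mean
MVC of the three is the definitive score, normalised to relative
strength in N/kg by body mass.

Sign convention (fixed here because the device describes directions only
verbally): on Fx, outward push is positive, so A (inward pull) carries
effort sign -1 and B (outward push) +1; on Fy, forward push is positive,
so D1/K1 carry +1 and the backward pulls D2/K2 carry -1.  The windowed
mean is computed on the direction-signed component, never on the
absolute value — push and pull are distinct tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import (
    ForceTrace,
    MvcResult,
    PreprocessConfig,
    best_of_trials,
    lowpass_channel,
    sliding_window_mvc,
)

__all__ = [
    "Direction",
    "DIRECTIONS",
    "DIRECTION_CODES",
    "Participant",
    "Trial",
    "AssessmentResult",
    "ProtocolError",
    "mass_from_fz",
    "extract_trial",
    "run_assessment",
    "STANDARD_GRAVITY",
]

STANDARD_GRAVITY = 9.81  # m/s^2


class ProtocolError(ValueError):
    """Protocol violation or inconsistent participant record."""


@dataclass(frozen=True)
class Direction:
    code: str
    plane: str  # "frontal" | "sagittal"
    axis: str  # "fx" | "fy"
    effort_sign: int  # +1 | -1
    front_leg: str  # "right" | "left" | "both"
    description: str = ""


DIRECTIONS: dict[str, Direction] = {
    "A": Direction("A", "frontal", "fx", -1, "both", "adduction: pull legs inward"),
    "B": Direction("B", "frontal", "fx", +1, "both", "abduction: push legs outward"),
    "D1": Direction("D1", "sagittal", "fy", +1, "right", "right leg forward, push"),
    "D2": Direction("D2", "sagittal", "fy", -1, "right", "right leg forward, pull"),
    "K1": Direction("K1", "sagittal", "fy", +1, "left", "left leg forward, push"),
    "K2": Direction("K2", "sagittal", "fy", -1, "left", "left leg forward, pull"),
}

DIRECTION_CODES = tuple(DIRECTIONS)

AGE_GROUP_RANGES = {"G25": (20, 30), "G45": (40, 50), "G65": (60, 70)}
AGE_GROUPS = tuple(AGE_GROUP_RANGES)
SEXES = ("male", "female")


def age_group_of(age: float) -> str:
    for group, (lo, hi) in AGE_GROUP_RANGES.items():
        if lo <= age <= hi:
            return group
    raise ProtocolError(f"age {age} falls outside the study's age brackets")


@dataclass(frozen=True)
class Participant:
    """One study participant; mass in kg is the normalisation denominator."""

    id: str
    sex: str
    age: float
    height: float  # cm
    mass: float  # kg
    age_group: str = ""
    bmi: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ProtocolError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.height <= 0 or self.mass <= 0:
            raise ProtocolError("height and mass must be positive")
        group = self.age_group or age_group_of(self.age)
        if group not in AGE_GROUP_RANGES:
            raise ProtocolError(f"unknown age group {group!r}")
        lo, hi = AGE_GROUP_RANGES[group]
        if not lo <= self.age <= hi:
            raise ProtocolError(
                f"age {self.age} inconsistent with group {group} [{lo}, {hi}]"
            )
        object.__setattr__(self, "age_group", group)
        bmi = self.mass / (self.height / 100.0) ** 2
        if self.bmi and abs(self.bmi - bmi) > 0.1:
            raise ProtocolError(
                f"stated BMI {self.bmi} inconsistent with mass/height ({bmi:.2f})"
            )
        object.__setattr__(self, "bmi", round(bmi, 2))

    @property
    def stratum(self) -> tuple[str, str]:
        return (self.sex, self.age_group)


@dataclass(frozen=True)
class Trial:
    """One maximal effort in one direction, with its extracted MVC."""

    direction: Direction
    mvc: float  # newtons, after effort-sign rectification
    result: MvcResult
    rest_before: float = 60.0  # seconds, recorded metadata only


@dataclass
class AssessmentResult:
    """Per-participant six-direction scores: best MVC (N) and relative (N/kg)."""

    participant: Participant
    best_mvc: dict[str, float] = field(default_factory=dict)
    relative: dict[str, float] = field(default_factory=dict)

    def complete(self) -> bool:
        return set(self.best_mvc) == set(DIRECTION_CODES)


def mass_from_fz(quiet_stance: ForceTrace, g: float = STANDARD_GRAVITY) -> float:
    """Body mass from the vertical force during quiet standing: mean(Fz)/g.

    Requires at least one second of stance and a strictly positive Fz
    throughout (the subject must actually be standing on the platform).
    """
    if quiet_stance.duration < 1.0:
        raise ProtocolError(
            f"quiet stance of {quiet_stance.duration:.2f} s is shorter than 1 s"
        )
    fz = quiet_stance.fz
    if np.any(fz <= 0):
        raise ProtocolError("Fz is not positive throughout; subject not standing")
    return float(fz.mean()) / g


def extract_trial(
    trace: ForceTrace,
    direction: Direction | str,
    cfg: PreprocessConfig | None = None,
) -> Trial:
    """Extract one trial's MVC: select axis, rectify sign, filter, window.

    Only the direction's mapped axis is consulted; the other channels are
    ignored entirely.
    """
    if isinstance(direction, str):
        direction = DIRECTIONS[direction]
    cfg = cfg or PreprocessConfig()
    raw = trace.channel(direction.axis) * direction.effort_sign
    filtered = lowpass_channel(raw, trace.fs, cfg)
    result = sliding_window_mvc(filtered, trace.fs, cfg, channel=direction.axis)
    return Trial(direction=direction, mvc=result.mvc, result=result)


def run_assessment(
    participant: Participant,
    trials: Mapping[str, Sequence[ForceTrace]],
    cfg: PreprocessConfig | None = None,
    mass: float | None = None,
    trials_per_direction: int = 3,
    allow_partial: bool = False,
) -> AssessmentResult:
    """Full six-direction assessment: best of three MVCs per direction, normalised.

    ``trials`` maps direction code -> the direction's force traces.  The
    protocol demands exactly three trials per direction and all six
    directions; ``allow_partial`` relaxes the trial count to 1–3 for
    clinical use.  ``mass`` defaults to the participant record's mass;
    pass a value from :func:`mass_from_fz` to normalise by measured
    vertical load instead.
    """
    cfg = cfg or PreprocessConfig()
    mass = participant.mass if mass is None else mass
    missing = set(DIRECTION_CODES) - set(trials)
    if missing:
        raise ProtocolError(f"missing directions: {sorted(missing)}")
    result = AssessmentResult(participant=participant)
    for code in DIRECTION_CODES:
        traces = list(trials[code])
        n = len(traces)
        ok = (1 <= n <= trials_per_direction) if allow_partial else (n == trials_per_direction)
        if not ok:
            raise ProtocolError(
                f"direction {code}: expected "
                f"{'1-' + str(trials_per_direction) if allow_partial else trials_per_direction}"
                f" trials, got {n}"
            )
        mvcs = [extract_trial(t, code, cfg).mvc for t in traces]
        best = best_of_trials(mvcs)
        result.best_mvc[code] = best
        result.relative[code] = best / mass
    return result
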