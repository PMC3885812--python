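"""Corridor-and-doorway world: geometry, reward schedule, collision rules.

The agent is a disc of diameter 1 m walking a 4 m x 10 m corridor toward a
doorway centred at (0, 10).  Passing through the opening pays a reward;
clipping a door post or a side wall is punished.  ``evaluate_step``
classifies a displacement; whether a wall contact ends the pass is the
episode runner's policy (by default it does not — the agent is reflected
back into the corridor).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DOOR_WIDTHS",
    "TrackGeometry",
    "RewardSchedule",
    "Cause",
    "StepOutcome",
    "reset_start",
    "evaluate_step",
]

#: Door widths (m) used for the wide / medium / narrow conditions.
DOOR_WIDTHS = {"wide": 3.0, "medium": 2.5, "narrow": 2.0}


@dataclass(frozen=True)
class TrackGeometry:
    """Corridor geometry with a doorway centred on x = 0 at ``y_door``.

    ``d_pos`` is the door half-width (d_length / 2); the opening spans
    x in [-d_pos, d_pos].
    """

    d_length: float = 2.0
    x_min: float = -2.0
    x_max: float = 2.0
    y_start: float = 0.0
    y_door: float = 10.0
    agent_radius: float = 0.5

    @property
    def d_pos(self) -> float:
        return self.d_length / 2.0

    def __post_init__(self) -> None:
        if self.d_pos <= self.agent_radius:
            raise ValueError(
                f"door half-width {self.d_pos} must exceed agent radius "
                f"{self.agent_radius} for the door to be passable"
            )
        if not (self.x_min < -self.d_pos < self.d_pos < self.x_max):
            raise ValueError("door must fit strictly inside the track breadth")

    @classmethod
    def from_preset(cls, name: str, **kwargs) -> "TrackGeometry":
        return cls(d_length=DOOR_WIDTHS[name], **kwargs)


@dataclass(frozen=True)
class RewardSchedule:
    """r = +5 for passage through the opening, -1 for any collision, 0 elsewhere."""

    r_pass: float = 5.0
    r_collision: float = -1.0
    r_elsewhere: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_pass > 0 > self.r_collision):
            raise ValueError("expected r_pass > 0 > r_collision")


class Cause(str, enum.Enum):
    ONGOING = "ongoing"
    PASSED_DOOR = "passed_door"
    HIT_DOOR_POST = "hit_door_post"
    HIT_WALL = "hit_wall"
    MAX_STEPS = "max_steps"


@dataclass(frozen=True)
class StepOutcome:
    reward: float
    cause: Cause

    @property
    def terminal(self) -> bool:
        return self.cause is not Cause.ONGOING


def reset_start(geometry: TrackGeometry, rng: np.random.Generator) -> np.ndarray:
    """Start-of-pass position: y = 0.1, x uniform where the disc fits."""
    half = geometry.x_max - geometry.agent_radius
    x = rng.uniform(-half, half)
    return np.array([x, geometry.y_start + 0.1])


def evaluate_step(
    geometry: TrackGeometry,
    schedule: RewardSchedule,
    old_position: np.ndarray,
    new_position: np.ndarray,
) -> StepOutcome:
    """Classify one displacement: wall hit, door-line crossing, or ongoing.

    The door-line test is applied at the x where the step's line segment
    crosses y_door; the disc passes iff |x| <= d_pos - agent_radius there.
    """
    x0, y0 = float(old_position[0]), float(old_position[1])
    x1, y1 = float(new_position[0]), float(new_position[1])

    if y0 < geometry.y_door <= y1:
        if y1 == y0:  # pragma: no cover - guarded by the inequality above
            x_cross = x1
        else:
            t = (geometry.y_door - y0) / (y1 - y0)
            x_cross = x0 + t * (x1 - x0)
        if abs(x_cross) <= geometry.d_pos - geometry.agent_radius:
            return StepOutcome(schedule.r_pass, Cause.PASSED_DOOR)
        return StepOutcome(schedule.r_collision, Cause.HIT_DOOR_POST)

    if abs(x1) > geometry.x_max - geometry.agent_radius:
        return StepOutcome(schedule.r_collision, Cause.HIT_WALL)

    return StepOutcome(schedule.r_elsewhere, Cause.ONGOING)
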