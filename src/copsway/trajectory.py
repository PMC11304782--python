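"""Domain types for center-of-pressure (COP) recordings.

A stabilometer (force platform) reports the planar point of application of
the ground-reaction force at a fixed rate; its trajectory quantifies standing
body sway.  Coordinates follow the convention used throughout this package:

* ``x`` — lateral COP displacement in mm, positive toward the participant's
  **left**;
* ``y`` — anterior–posterior (AP) displacement in mm, positive **anterior**.

With this convention a sway ellipse tilted toward the participant's left has
a positive declination (angle measured from the +y midline toward +x).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ValidationError

#: Closed vocabulary of measurement conditions: quiet stance, far-field
#: stimulation by the speaker array alone, and the array combined with each
#: of the three headphone types.
CONDITIONS = ("silent", "array_only", "bone", "closed", "ears_free")

#: Conditions in which a near-field device is worn (measured twice each).
HEADPHONE_CONDITIONS = ("bone", "closed", "ears_free")


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CopTrajectory:
    """One participant x condition x trial COP record.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    x, y : array of float
        Lateral (+left) and AP (+anterior) COP displacement in mm.
    participant_id : str
        Identifier; ``"unknown"`` when absent from file metadata.
    condition : str
        One of :data:`CONDITIONS`.
    trial_index : int
        1 or 2.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    condition: str
    participant_id: str = "unknown"
    trial_index: int = 1

    def __post_init__(self) -> None:
        t = _as_float_array(self.t, "t")
        x = _as_float_array(self.x, "x")
        y = _as_float_array(self.y, "y")
        if not (len(t) == len(x) == len(y)):
            raise ValidationError(
                f"t, x, y must have equal length, got {len(t)}, {len(x)}, {len(y)}"
            )
        if len(t) < 3:
            raise ValidationError(f"trajectory needs at least 3 samples, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("t must be strictly increasing")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.trial_index not in (1, 2):
            raise ValidationError(f"trial_index must be 1 or 2, got {self.trial_index}")
        for name, arr in (("t", t), ("x", x), ("y", y)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record span in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (lateral, AP) displacements in mm."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class StimulusSchedule:
    """Timing of the left/right panning stimuli within one trial.

    Ten pannings of 1,000 ms, alternating left-to-right and right-to-left
    starting left-to-right, separated by 5-s pauses so the evoked sway from
    one panning has died out before the next begins.
    """

    stimulus_duration_ms: float = 1000.0
    n_pannings: int = 10
    pause_s: float = 5.0
    first_direction: str = "LR"

    def __post_init__(self) -> None:
        if self.stimulus_duration_ms <= 0:
            raise ValidationError("stimulus_duration_ms must be positive")
        if self.pause_s <= 0:
            raise ValidationError("pause_s must be positive")
        if self.n_pannings <= 0 or self.n_pannings % 2 != 0:
            raise ValidationError(
                f"n_pannings must be a positive even count, got {self.n_pannings}"
            )
        if self.first_direction not in ("LR", "RL"):
            raise ValidationError("first_direction must be 'LR' or 'RL'")

    @property
    def stimulus_duration_s(self) -> float:
        return self.stimulus_duration_ms / 1000.0

    @property
    def total_duration_s(self) -> float:
        """Time from the first onset to the end of the last panning."""
        n = self.n_pannings
        return n * self.stimulus_duration_s + (n - 1) * self.pause_s

    def onset_times(self) -> np.ndarray:
        """Onset of each panning, in seconds from the start of the record."""
        period = self.stimulus_duration_s + self.pause_s
        return np.arange(self.n_pannings) * period

    def directions(self) -> tuple[str, ...]:
        """Panning direction per onset, alternating from ``first_direction``."""
        other = "RL" if self.first_direction == "LR" else "LR"
        return tuple(
            self.first_direction if k % 2 == 0 else other
            for k in range(self.n_pannings)
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol-level configuration for a measurement campaign.

    ``sound_levels`` is inert metadata (system-side level in dBSSL and the
    sound-level-meter reading in dBSPL per condition); it plays no role in
    any computation here.
    """

    conditions: tuple[str, ...] = CONDITIONS
    trials_per_condition: int = 2
    record_duration_s: float = 60.0
    sampling_rate_hz: float = 100.0
    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)
    sound_levels: Mapping[str, Mapping[str, float | None]] | None = None

    def __post_init__(self) -> None:
        conditions = tuple(self.conditions)
        for c in conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r} in config")
        if len(set(conditions)) != len(conditions):
            raise ValidationError("duplicate condition in config")
        object.__setattr__(self, "conditions", conditions)
        if self.trials_per_condition < 1:
            raise ValidationError("trials_per_condition must be >= 1")
        if self.record_duration_s <= 0:
            raise ValidationError("record_duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.record_duration_s < self.schedule.total_duration_s:
            raise ValidationError(
                "record_duration_s shorter than the stimulus schedule "
                f"({self.record_duration_s} s < {self.schedule.total_duration_s} s)"
            )
        if self.sound_levels is not None:
            for c in self.sound_levels:
                if c not in CONDITIONS:
                    raise ValidationError(f"sound_levels for unknown condition {c!r}")

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)
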