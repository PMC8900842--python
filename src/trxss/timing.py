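"""Trigger-scheme arithmetic for pump-probe acquisition.

The detector free-runs at ``frame_rate`` for ``step_duration`` seconds per
step; each frame integrates for one period minus the readout dead time.  In a
laser-on step the primary IR pulse (duration ``tw1``) arrives ``dt1`` seconds
after acquisition starts; an optional train of short secondary pulses
(duration ``tw2`` at ``secondary_rate`` for ``train_duration``) follows to
maintain the temperature jump.  ``dt2`` is measured from the *start* of the
primary pulse, which keeps a single unambiguous time origin (the reference
point for the secondary delay is otherwise a documented convention, not a
physical constraint).

Frame binning is half-open: frame k covers [k/rate, (k+1)/rate), so an event
landing exactly on a frame boundary belongs to the later frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidArgumentError, ValidationError

__all__ = [
    "TriggerScheme",
    "frames_per_step",
    "frame_live_time",
    "pulse_schedule",
    "time_to_frame",
]

# tolerance absorbing float representation error in time*rate products
_EPS = 1e-9


@dataclass(frozen=True)
class TriggerScheme:
    """Timing of one acquisition step (all times in seconds, rates in Hz)."""

    frame_rate: float = 500.0
    readout_dead_time: float = 100e-6
    step_duration: float = 4.0
    dt1: float = 1.0            # delay from acquisition start to primary pulse
    tw1: float = 2e-3           # primary pulse duration
    dt2: float = 2e-3           # delay from primary-pulse start to first secondary
    tw2: float = 50e-6          # secondary pulse duration
    secondary_rate: float = 90.0
    train_duration: float = 0.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not 0 <= self.readout_dead_time < 1.0 / self.frame_rate:
            raise ValidationError(
                f"readout dead time {self.readout_dead_time} s must lie in "
                f"[0, frame period {1.0 / self.frame_rate} s)"
            )
        if self.step_duration < 0:
            raise ValidationError("step_duration must be >= 0")
        if self.dt1 < 0 or self.tw1 < 0 or self.dt2 < 0 or self.tw2 < 0:
            raise ValidationError("delays and pulse durations must be >= 0")
        if self.dt1 + self.tw1 > self.step_duration + _EPS:
            raise ValidationError(
                f"primary pulse (dt1 + tw1 = {self.dt1 + self.tw1} s) extends "
                f"past step end ({self.step_duration} s)"
            )
        if self.train_duration > 0:
            if self.secondary_rate <= 0:
                raise ValidationError("secondary_rate must be > 0 when a train is used")
            n_sec = math.floor(self.train_duration * self.secondary_rate + _EPS)
            if n_sec > 0:
                last_end = (self.dt1 + self.dt2
                            + (n_sec - 1) / self.secondary_rate + self.tw2)
                if last_end > self.step_duration + _EPS:
                    raise ValidationError(
                        f"secondary pulse train extends past step end "
                        f"(last pulse ends at {last_end} s of {self.step_duration} s)"
                    )

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate

    def frames_per_step(self) -> int:
        return frames_per_step(self)

    def frame_live_time(self) -> float:
        return frame_live_time(self)

    def pulse_schedule(self) -> list[tuple[float, float]]:
        return pulse_schedule(self)

    def frame_times(self) -> np.ndarray:
        """Exposure-start times of every frame in a step, s."""
        return np.arange(self.frames_per_step()) * self.frame_period

    # -- serialization (scan manifests, pipeline configs) -------------------

    _KEYMAP = {
        "frame_rate": "frame_rate_hz",
        "readout_dead_time": "readout_s",
        "step_duration": "step_s",
        "dt1": "dt1_s",
        "tw1": "tw1_s",
        "dt2": "dt2_s",
        "tw2": "tw2_s",
        "secondary_rate": "secondary_rate_hz",
        "train_duration": "train_s",
    }

    def to_dict(self) -> dict:
        d = asdict(self)
        return {self._KEYMAP[k]: float(v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TriggerScheme":
        inv = {v: k for k, v in cls._KEYMAP.items()}
        kwargs = {}
        for key, value in d.items():
            if key in inv:
                kwargs[inv[key]] = float(value)
            elif key in cls._KEYMAP:  # accept field names too
                kwargs[key] = float(value)
            else:
                raise InvalidArgumentError(f"unknown trigger-scheme key {key!r}")
        return cls(**kwargs)


def frames_per_step(scheme: TriggerScheme) -> int:
    """Number of complete frames in one step: floor(step_duration * frame_rate)."""
    return int(math.floor(scheme.step_duration * scheme.frame_rate + _EPS))


def frame_live_time(scheme: TriggerScheme) -> float:
    """Per-frame integration time: frame period minus readout dead time, s."""
    return scheme.frame_period - scheme.readout_dead_time


def pulse_schedule(scheme: TriggerScheme) -> list[tuple[float, float]]:
    """Laser pulses of one on-step as (start, duration) pairs, s from step start.

    The primary pulse at (dt1, tw1) is followed, when ``train_duration > 0``,
    by ``floor(train_duration * secondary_rate)`` secondary pulses starting at
    ``dt1 + dt2 + k / secondary_rate``.
    """
    pulses = [(scheme.dt1, scheme.tw1)]
    if scheme.train_duration > 0:
        n_sec = int(math.floor(scheme.train_duration * scheme.secondary_rate + _EPS))
        t0 = scheme.dt1 + scheme.dt2
        for k in range(n_sec):
            pulses.append((t0 + k / scheme.secondary_rate, scheme.tw2))
    for start, duration in pulses:
        if start + duration > scheme.step_duration + _EPS:
            raise ValidationError(
                f"pulse at {start} s (duration {duration} s) extends past "
                f"step end ({scheme.step_duration} s)"
            )
    return pulses


def time_to_frame(t: float, scheme: TriggerScheme) -> int:
    """Frame index whose half-open window [k/rate, (k+1)/rate) contains t."""
    if not 0 <= t < scheme.step_duration:
        raise InvalidArgumentError(
            f"t={t} s outside the step's half-open interval [0, {scheme.step_duration})"
        )
    k = int(math.floor(t * scheme.frame_rate + _EPS))
    return min(k, frames_per_step(scheme) - 1)
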