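"""Domain types for a single juxtacellular recording session.

A session is one recorded cell: its spike train, optionally the animal's
head-tracking trace (two head-mounted LEDs) while it explored the maze,
optionally the light-pulse protocol delivered at the end of the recording,
and free-form annotations (e.g. histology results).

Conventions: times are seconds (float64), positions are centimetres with the
origin at the lower-left corner of the arena bounding box.  Missing tracking
samples are NaN and are dropped (never interpolated) before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import MazeGeometry


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class SpikeTrain:
    """Spike event times within a recording span.

    times must be strictly increasing (duplicate timestamps rejected) and lie
    within ``recording_span = (t0, t1)``.
    """

    times: np.ndarray
    recording_span: tuple

    def __post_init__(self):
        self.times = _as_1d_float(self.times, "spike times")
        t0, t1 = (float(self.recording_span[0]), float(self.recording_span[1]))
        self.recording_span = (t0, t1)
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.recording_span
        if not t1 > t0:
            raise ValidationError(f"recording_span must be increasing, got {self.recording_span}")
        if self.times.size:
            if np.any(~np.isfinite(self.times)):
                raise ValidationError("spike times must be finite")
            if np.any(np.diff(self.times) <= 0):
                raise ValidationError("spike times must be strictly increasing")
            if self.times[0] < t0 or self.times[-1] > t1:
                raise ValidationError("spike times must lie within recording_span")

    @property
    def duration_s(self) -> float:
        return self.recording_span[1] - self.recording_span[0]

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class TrackingTrace:
    """Two-LED head tracking at a regular frame interval.

    ``led1_xy`` and ``led2_xy`` are (n, 2) arrays in cm; missing samples are
    NaN.  The frame interval must be constant to within 1%.
    """

    t: np.ndarray
    led1_xy: np.ndarray
    led2_xy: np.ndarray

    def __post_init__(self):
        self.t = _as_1d_float(self.t, "tracking times")
        self.led1_xy = np.asarray(self.led1_xy, dtype=float)
        self.led2_xy = np.asarray(self.led2_xy, dtype=float)
        self.validate()

    def validate(self, arena: Optional[MazeGeometry] = None) -> None:
        for name, led in (("led1_xy", self.led1_xy), ("led2_xy", self.led2_xy)):
            if led.shape != (self.t.size, 2):
                raise ValidationError(f"{name} must have shape (n_samples, 2)")
        if self.t.size < 2:
            raise ValidationError("tracking requires at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("tracking times must be strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise ValidationError("tracking frame interval must be constant within 1%")
        if arena is not None:
            (w, h) = arena.bounding_box_cm
            for name, led in (("led1_xy", self.led1_xy), ("led2_xy", self.led2_xy)):
                ok = np.isnan(led).any(axis=1)
                xy = led[~ok]
                if xy.size and (
                    xy[:, 0].min() < -1e-9 or xy[:, 0].max() > w + 1e-9
                    or xy[:, 1].min() < -1e-9 or xy[:, 1].max() > h + 1e-9
                ):
                    raise ValidationError(f"{name} coordinates fall outside the arena bounding box")

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float(np.median(np.diff(self.t)))

    @property
    def span(self) -> tuple:
        return (float(self.t[0]), float(self.t[-1]))


@dataclass
class LightPulseTrain:
    """Blue-light stimulation pulses: onset, duration, power and the nominal
    frequency of the train each pulse belongs to."""

    onsets: np.ndarray
    duration_ms: np.ndarray
    power_mW: np.ndarray
    train_frequency_Hz: np.ndarray

    def __post_init__(self):
        self.onsets = _as_1d_float(self.onsets, "pulse onsets")
        n = self.onsets.size
        for name in ("duration_ms", "power_mW", "train_frequency_Hz"):
            val = np.asarray(getattr(self, name), dtype=float)
            if val.ndim == 0:
                val = np.full(n, float(val))
            setattr(self, name, val)
        self.validate()

    def validate(self) -> None:
        n = self.onsets.size
        for name in ("duration_ms", "power_mW", "train_frequency_Hz"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} must match the number of pulses")
        if n and np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("pulse onsets must be strictly increasing")
        if np.any(self.duration_ms <= 0):
            raise ValidationError("pulse durations must be positive")
        if np.any(self.power_mW <= 0):
            raise ValidationError("pulse powers must be positive")

    @property
    def n_pulses(self) -> int:
        return int(self.onsets.size)

    def subset(self, mask: np.ndarray) -> "LightPulseTrain":
        return LightPulseTrain(
            onsets=self.onsets[mask],
            duration_ms=self.duration_ms[mask],
            power_mW=self.power_mW[mask],
            train_frequency_Hz=self.train_frequency_Hz[mask],
        )


@dataclass
class SessionRecord:
    """One recording session (one cell).

    Tracking and pulses are optional; when present, their time ranges must lie
    within the spike train's recording span (pulses are typically delivered
    after exploration, so tracking and pulse spans need not overlap each
    other).
    """

    session_id: str
    spikes: SpikeTrain
    tracking: Optional[TrackingTrace] = None
    pulses: Optional[LightPulseTrain] = None
    arena: Optional[MazeGeometry] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.session_id:
            raise ValidationError("session_id must be non-empty")
        t0, t1 = self.spikes.recording_span
        tol = 1e-9
        if self.tracking is not None:
            a, b = self.tracking.span
            if a < t0 - tol or b > t1 + tol:
                raise ValidationError("tracking time range must lie within recording_span")
            self.tracking.validate(self.arena)
        if self.pulses is not None and self.pulses.n_pulses:
            if self.pulses.onsets[0] < t0 - tol or self.pulses.onsets[-1] > t1 + tol:
                raise ValidationError("pulse onsets must lie within recording_span")
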