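"""Shared domain types for latency traces, stimulation protocols and events.

All quantities are normalized at the boundary to fixed units: seconds for
time, milliseconds for conduction latency, millimetres for conduction
distance, grams for von Frey force and cm^2 for skin areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: C-fibers are identified by a conduction velocity below this bound (m/s).
C_FIBER_MAX_CV_M_PER_S = 2.0

EVENT_KINDS = ("injection", "spicule", "mechanical", "iontophoresis")


class ValidationError(ValueError):
    """A domain invariant was violated while constructing or reading data."""


def conduction_velocity(distance_mm: float, latency_ms: float) -> float:
    """Conduction velocity in m/s from distance (mm) and latency (ms).

    mm/ms is numerically identical to m/s, so this is a plain ratio with
    domain checks.
    """
    if distance_mm <= 0:
        raise ValidationError(f"conduction distance must be > 0 mm, got {distance_mm}")
    if latency_ms <= 0:
        raise ValidationError(f"latency must be > 0 ms, got {latency_ms}")
    return distance_mm / latency_ms


@dataclass(frozen=True)
class StimulationProtocol:
    """Electrical stimulation protocol: phases of (pulse_count, frequency_hz).

    The default tracking frequency of 0.25 Hz is the rate used for
    continuous latency tracking; intensity is expressed as a multiple of
    the fiber's individual electrical threshold.
    """

    phases: tuple[tuple[int, float], ...] = ()
    tracking_frequency_hz: float = 0.25
    intensity_factor: float = 1.5

    def __post_init__(self) -> None:
        for count, freq in self.phases:
            if count <= 0:
                raise ValidationError(f"pulse count must be > 0, got {count}")
            if freq <= 0:
                raise ValidationError(f"frequency must be > 0 Hz, got {freq}")
        if self.tracking_frequency_hz <= 0:
            raise ValidationError("tracking frequency must be > 0 Hz")
        if self.intensity_factor <= 0:
            raise ValidationError("intensity factor must be > 0")

    def phase_pulse_count(self) -> int:
        return sum(count for count, _ in self.phases)

    def stimulus_times(self, t0: float = 0.0, n_tracking: int = 0) -> np.ndarray:
        """Stimulus times (s): all protocol phases, then ``n_tracking``
        pulses at the tracking frequency."""
        times: list[float] = []
        t = t0
        for count, freq in self.phases:
            dt = 1.0 / freq
            for _ in range(count):
                times.append(t)
                t += dt
        dt = 1.0 / self.tracking_frequency_hz
        for _ in range(n_tracking):
            times.append(t)
            t += dt
        return np.asarray(times, dtype=float)


#: Rising-frequency protocol used for ADS-based fiber classification.
CLASSIFICATION_PROTOCOL = StimulationProtocol(
    phases=((20, 0.125), (20, 0.25), (30, 0.5))
)


@dataclass(frozen=True)
class Event:
    kind: str
    t_start: float
    t_end: float
    magnitude: Optional[float] = None  # von Frey force in g for mechanical

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(
                f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}"
            )
        if self.t_start > self.t_end:
            raise ValidationError(
                f"event t_start {self.t_start} > t_end {self.t_end}"
            )


@dataclass(frozen=True)
class EventLog:
    entries: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        starts = [e.t_start for e in self.entries]
        if starts != sorted(starts):
            raise ValidationError("event log entries must be sorted by t_start")

    def first_of_kind(self, kind: str) -> Optional[Event]:
        for e in self.entries:
            if e.kind == kind:
                return e
        return None


@dataclass
class LatencyTrace:
    """Time-stamped latencies of one electrically tracked C-fiber.

    ``latencies`` holds one entry per stimulus; conduction failures are
    explicit NaN gaps and are never interpolated.
    """

    fiber_id: str
    stimulus_times: np.ndarray  # s, strictly increasing
    latencies: np.ndarray  # ms, NaN = conduction failure
    conduction_distance_mm: float
    events: EventLog = field(default_factory=EventLog)
    protocol: Optional[StimulationProtocol] = None

    def __post_init__(self) -> None:
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        self.latencies = np.asarray(self.latencies, dtype=float)
        if self.stimulus_times.ndim != 1:
            raise ValidationError("stimulus_times must be one-dimensional")
        if self.latencies.shape != self.stimulus_times.shape:
            raise ValidationError(
                f"{len(self.latencies)} latencies for "
                f"{len(self.stimulus_times)} stimuli"
            )
        if len(self.stimulus_times) and np.any(np.diff(self.stimulus_times) <= 0):
            raise ValidationError("stimulus_times must be strictly increasing")
        if self.conduction_distance_mm <= 0:
            raise ValidationError("conduction_distance_mm must be > 0")
        present = ~np.isnan(self.latencies)
        if np.any(self.latencies[present] <= 0):
            idx = int(np.nonzero(present & (self.latencies <= 0))[0][0])
            raise ValidationError(f"non-positive latency at stimulus index {idx}")
        cv = self.conduction_distance_mm / self.latencies[present]
        if np.any(cv >= C_FIBER_MAX_CV_M_PER_S):
            bad = np.nonzero(present)[0][cv >= C_FIBER_MAX_CV_M_PER_S]
            raise ValidationError(
                "conduction velocity >= "
                f"{C_FIBER_MAX_CV_M_PER_S} m/s (not a C-fiber) at stimulus "
                f"indices {bad.tolist()}"
            )

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_times)

    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.latencies)

    def conduction_velocities(self) -> np.ndarray:
        """Per-stimulus conduction velocity in m/s (NaN at failures)."""
        return self.conduction_distance_mm / self.latencies

    def equals(self, other: "LatencyTrace") -> bool:
        return (
            self.fiber_id == other.fiber_id
            and self.conduction_distance_mm == other.conduction_distance_mm
            and np.array_equal(self.stimulus_times, other.stimulus_times)
            and np.array_equal(self.latencies, other.latencies, equal_nan=True)
            and self.events == other.events
        )


@dataclass(frozen=True)
class RatingSeries:
    """One subject's itch and pain NRS ratings on a uniform 10 s grid.

    Ratings are prompted values from {0, 0.5, 1, 2, ..., 10}; 0.5 encodes
    a sensation that is neither itchy nor painful.
    """

    subject_id: str
    substance: str
    application_mode: str  # injection | focal | iontophoresis
    times_s: tuple[float, ...]
    itch: tuple[float, ...]
    pain: tuple[float, ...]
    condition: str = "control"

    ALLOWED_RATINGS = frozenset([0.0, 0.5] + [float(k) for k in range(1, 11)])

    def __post_init__(self) -> None:
        if not self.times_s:
            raise ValidationError("rating series must contain at least one sample")
        if len(self.itch) != len(self.times_s) or len(self.pain) != len(self.times_s):
            raise ValidationError("itch/pain lengths must match the time grid")
        diffs = {round(b - a, 6) for a, b in zip(self.times_s, self.times_s[1:])}
        if len(diffs) > 1:
            raise ValidationError(
                f"non-uniform rating grid (spacings {sorted(diffs)}); "
                "resampling is refused"
            )
        for name, values in (("itch", self.itch), ("pain", self.pain)):
            for t, v in zip(self.times_s, values):
                if v not in self.ALLOWED_RATINGS:
                    raise ValidationError(
                        f"{name} rating {v} at t={t}s outside the allowed "
                        "NRS set {0, 0.5, 1, ..., 10}"
                    )

    @property
    def grid_s(self) -> float:
        if len(self.times_s) < 2:
            return math.nan
        return self.times_s[1] - self.times_s[0]


def as_rating_tuple(values: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in values)
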