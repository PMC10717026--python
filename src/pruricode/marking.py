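"""Marking-technique analysis of latency traces.

A C-fiber conducting extra (chemically evoked) action potentials slows
down, so the latency of the regularly evoked electrical test response
jumps ("marking").  This module detects those activation periods, sums
them into the cumulative latency shift, applies the strict > 5 ms
activation criterion, and recognizes the slow bursting discharge pattern:
at least three repetitions of a sudden latency increase (discharge train
within the previous 4 s) followed by at least 20 s -- five consecutive
tracked stimuli -- of silence with normalizing latencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pruricode.config import BurstingParams, MarkingThresholdPolicy
from pruricode.types import LatencyTrace, ValidationError

#: Event kinds whose end time marks the start of the analysis window
#: (chemical application; markings during needle-in time are not counted).
_APPLICATION_KINDS = ("injection", "spicule", "iontophoresis")


class AnalysisError(ValueError):
    """The trace cannot be analyzed as requested."""


@dataclass(frozen=True)
class ActivationPeriod:
    """One detected sudden latency increase."""

    stimulus_index: int
    time_s: float
    latency_shift_ms: float  # > detection threshold


@dataclass(frozen=True)
class ChemicalResponseSummary:
    fiber_id: str
    n_activation_periods: int
    cumulative_latency_ms: float
    activated: bool
    analysis_window: tuple[float, float]
    criterion_ms: float = 5.0


@dataclass(frozen=True)
class BurstRepetition:
    onset_index: int
    shift_ms: float
    silence_duration_s: float


@dataclass(frozen=True)
class BurstingAssessment:
    is_bursting: bool
    bursts: tuple[BurstRepetition, ...]
    params: BurstingParams = field(default_factory=BurstingParams)


def _application_end(trace: LatencyTrace) -> Optional[float]:
    for e in trace.events.entries:
        if e.kind in _APPLICATION_KINDS:
            return e.t_end
    return None


def estimate_baseline_jitter(
    trace: LatencyTrace, policy: MarkingThresholdPolicy, window_start: float
) -> float:
    """Jitter SD (ms) from the last ``baseline_window`` latencies before the
    analysis window, via consecutive differences (robust to slow drift)."""
    mask = trace.present_mask() & (trace.stimulus_times < window_start)
    baseline = trace.latencies[mask][-policy.baseline_window :]
    if len(baseline) < policy.baseline_window:
        raise AnalysisError(
            f"need {policy.baseline_window} pre-application latencies, "
            f"found {len(baseline)}"
        )
    diffs = np.diff(baseline)
    return float(np.std(diffs, ddof=1) / math.sqrt(2.0))


def detect_activation_periods(
    trace: LatencyTrace,
    policy: MarkingThresholdPolicy | None = None,
    *,
    window: Optional[tuple[float, float]] = None,
    window_s: float = 300.0,
) -> list[ActivationPeriod]:
    """Detect activation periods inside the analysis window.

    The window defaults to [application end, application end + window_s]:
    only markings after the syringe was removed count.  A period is
    reported at stimulus i iff

        latency(i) - latency(i-1) > max(absolute_floor, multiplier * sigma)

    where sigma is the baseline jitter estimate.  Conduction failures break
    adjacency: no comparison is made across a gap.
    """
    policy = policy or MarkingThresholdPolicy()
    if window is None:
        t_end = _application_end(trace)
        if t_end is None:
            raise AnalysisError(
                "no application event in the trace event log and no explicit window"
            )
        window = (t_end, t_end + window_s)
    if not np.any(trace.present_mask()):
        raise AnalysisError("trace contains no conducted responses")

    sigma = estimate_baseline_jitter(trace, policy, window[0])
    threshold = max(policy.absolute_floor_ms, policy.jitter_multiplier * sigma)

    lat = trace.latencies
    t = trace.stimulus_times
    periods: list[ActivationPeriod] = []
    for i in range(1, trace.n_stimuli):
        if not (window[0] <= t[i] <= window[1]):
            continue
        if math.isnan(lat[i]) or math.isnan(lat[i - 1]):
            continue  # gap breaks adjacency
        shift = lat[i] - lat[i - 1]
        if shift > threshold:
            periods.append(ActivationPeriod(i, float(t[i]), float(shift)))
    return periods


def summarize_chemical_response(
    periods: Sequence[ActivationPeriod],
    criterion_ms: float = 5.0,
    *,
    fiber_id: str = "",
    analysis_window: tuple[float, float] = (math.nan, math.nan),
) -> ChemicalResponseSummary:
    """Count and sum activation periods; 'activated' requires the cumulative
    latency shift to strictly exceed the criterion (default 5 ms)."""
    for p in periods:
        if p.latency_shift_ms <= 0:
            raise ValidationError(
                f"non-positive shift {p.latency_shift_ms} at index {p.stimulus_index}"
            )
    cumulative = float(sum(p.latency_shift_ms for p in periods))
    return ChemicalResponseSummary(
        fiber_id=fiber_id,
        n_activation_periods=len(periods),
        cumulative_latency_ms=cumulative,
        activated=cumulative > criterion_ms,
        analysis_window=analysis_window,
        criterion_ms=criterion_ms,
    )


def detect_slow_bursting(
    trace: LatencyTrace,
    periods: Sequence[ActivationPeriod],
    params: BurstingParams | None = None,
    *,
    policy: MarkingThresholdPolicy | None = None,
    window_start: Optional[float] = None,
    allow_any_tracking_frequency: bool = False,
) -> BurstingAssessment:
    """Classify the discharge pattern as slow bursting or not.

    A qualifying repetition is one activation period followed by at least
    ``n_silent_stimuli`` consecutive conducted responses with no further
    marking and non-increasing ("normalizing") latencies within one jitter
    SD.  A conduction failure inside the silent run invalidates it.  The
    pattern is called bursting at >= ``min_repetitions`` repetitions.
    """
    params = params or BurstingParams()
    policy = policy or MarkingThresholdPolicy()

    t = trace.stimulus_times
    lat = trace.latencies
    if len(t) > 1 and not allow_any_tracking_frequency:
        dt = float(np.median(np.diff(t)))
        if not math.isclose(dt, 4.0, rel_tol=0.01):
            raise AnalysisError(
                f"tracking interval {dt:.2f} s is not 4 s (0.25 Hz); the "
                "silence-in-seconds and silence-in-stimuli criteria would "
                "disagree -- pass allow_any_tracking_frequency=True to override"
            )

    if window_start is None:
        app_end = _application_end(trace)
        window_start = app_end if app_end is not None else float(t[0])
    try:
        sigma = estimate_baseline_jitter(trace, policy, window_start)
    except AnalysisError:
        sigma = 0.0
    tolerance = max(1e-9, sigma)

    period_idx = {p.stimulus_index for p in periods}
    bursts: list[BurstRepetition] = []
    for p in periods:
        i, n = p.stimulus_index, params.n_silent_stimuli
        if i + n >= trace.n_stimuli:
            continue
        run = range(i + 1, i + n + 1)
        if any(math.isnan(lat[j]) for j in run):
            continue  # failure inside the silent run: conservative, not counted
        if any(j in period_idx for j in run):
            continue
        if any(lat[j] - lat[j - 1] > tolerance for j in run):
            continue  # latencies must normalize (non-increasing within jitter)
        silence = float(t[i + n] - t[i])
        if silence < params.min_silence_s:
            continue
        bursts.append(BurstRepetition(i, p.latency_shift_ms, silence))

    return BurstingAssessment(
        is_bursting=len(bursts) >= params.min_repetitions,
        bursts=tuple(bursts),
        params=params,
    )


def activation_table(
    records: Sequence[dict],
) -> pd.DataFrame:
    """Aggregate per-fiber response records into a per-(class, substance)
    activation table.

    Each record needs ``class_label``, ``substance``, ``activated`` and
    ``bursting`` keys.  Percentages are rounded to one decimal.
    """
    for i, rec in enumerate(records):
        for key in ("class_label", "substance", "activated", "bursting"):
            if key not in rec:
                raise ValidationError(f"record {i} lacks {key!r}")
    frame = pd.DataFrame(list(records))
    if frame.empty:
        return pd.DataFrame(
            columns=[
                "class_label", "substance", "n_tested", "n_activated",
                "pct_activated", "n_bursting", "pct_bursting",
            ]
        )
    grouped = (
        frame.groupby(["class_label", "substance"])
        .agg(
            n_tested=("activated", "size"),
            n_activated=("activated", "sum"),
            n_bursting=("bursting", "sum"),
        )
        .reset_index()
    )
    grouped["pct_activated"] = (100.0 * grouped.n_activated / grouped.n_tested).round(1)
    grouped["pct_bursting"] = (100.0 * grouped.n_bursting / grouped.n_tested).round(1)
    return grouped[
        ["class_label", "substance", "n_tested", "n_activated", "pct_activated",
         "n_bursting", "pct_bursting"]
    ]


def activation_percentage(n_activated: int, n_tested: int, decimals: int = 1) -> float:
    """Activated share of tested fibers, as a percentage."""
    if n_tested <= 0:
        raise ValidationError("n_tested must be positive")
    return round(100.0 * n_activated / n_tested, decimals)
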