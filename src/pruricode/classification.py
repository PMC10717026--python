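"""CM / CMi / VHT fiber classification from the rising-frequency ADS run.

The decision rule:

* CM:  ADS < 5% of initial latency, recovery > 24% within 40 s, and a
  mechanical response below 22 g von Frey force.
* CMi: ADS > 5% and recovery < 24%, no mechanical response.
* VHT: ADS > 5% and recovery < 24%, mechanical response only above 10 g.

All comparators are strict; inputs on a boundary or in an uncovered region
(e.g. ADS < 5% with recovery < 24%) are flagged 'unclassifiable' rather
than silently coerced.  The recovery percentage is expressed as the share
of the accrued slowing (peak minus initial latency) recovered within the
40 s window; see docs/methods.md for why percent-of-initial-latency would
make the CM criteria mutually unsatisfiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pruricode.config import ClassificationParams
from pruricode.types import CLASSIFICATION_PROTOCOL, LatencyTrace, ValidationError

#: Stiff von Frey filament forces (g) used for mechanical testing.
VON_FREY_FORCES_G = (1.2, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 22.0)

CLASS_LABELS = ("CM", "CMi", "VHT", "unclassifiable")


class ProtocolError(ValueError):
    """The trace does not contain the full classification protocol."""


@dataclass(frozen=True)
class ADSMetrics:
    initial_latency_ms: float
    peak_latency_ms: float
    ads_percent: float  # 100 * (peak - initial) / initial
    recovery_percent: float  # share of accrued slowing recovered in the window
    recovery_window_s: float = 40.0


@dataclass(frozen=True)
class MechanicalProfile:
    """Result of von Frey testing; ``lowest_responding_force_g`` is None
    for fibers with no mechanical response at any tested force."""

    tested_forces_g: tuple[float, ...] = VON_FREY_FORCES_G
    lowest_responding_force_g: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.lowest_responding_force_g is not None
            and self.lowest_responding_force_g not in self.tested_forces_g
        ):
            raise ValidationError(
                f"lowest responding force {self.lowest_responding_force_g} g "
                "is not one of the tested forces"
            )


@dataclass(frozen=True)
class FiberClassification:
    fiber_id: str
    class_label: str
    metrics: ADSMetrics
    mech: MechanicalProfile


def compute_ads_metrics_from_arrays(
    stimulus_times: np.ndarray,
    latencies: np.ndarray,
    params: ClassificationParams | None = None,
) -> ADSMetrics:
    """ADS metrics from raw arrays covering the 70-pulse rising-frequency
    protocol plus post-protocol tracking.

    Initial latency is the mean of the first ``initial_latency_pulses``
    responses; peak is the response to the last protocol pulse; recovery is
    read at the first tracked stimulus at least ``recovery_window_s`` after
    the end of the protocol.
    """
    params = params or ClassificationParams()
    n_protocol = CLASSIFICATION_PROTOCOL.phase_pulse_count()
    phases = CLASSIFICATION_PROTOCOL.phases
    n_seen = len(stimulus_times)
    cum = 0
    for count, freq in phases:
        cum += count
        if n_seen < cum:
            raise ProtocolError(
                f"protocol incomplete: {freq} Hz phase needs stimuli up to "
                f"#{cum}, trace has {n_seen}"
            )

    initial = float(np.nanmean(latencies[: params.initial_latency_pulses]))
    peak = float(latencies[n_protocol - 1])
    if math.isnan(peak):
        raise ProtocolError("conduction failure at the last protocol pulse")
    protocol_end = float(stimulus_times[n_protocol - 1])

    post = np.arange(n_protocol, n_seen)
    eligible = [
        i
        for i in post
        if stimulus_times[i] >= protocol_end + params.recovery_window_s
        and not math.isnan(latencies[i])
    ]
    if not eligible:
        raise ProtocolError(
            f"no tracked stimulus >= {params.recovery_window_s} s after the "
            "protocol; post-protocol tracking incomplete"
        )
    l40 = float(latencies[eligible[0]])

    ads_percent = 100.0 * (peak - initial) / initial
    accrued = peak - initial
    recovery_percent = 100.0 * (peak - l40) / accrued if accrued > 0 else 0.0
    return ADSMetrics(
        initial_latency_ms=initial,
        peak_latency_ms=peak,
        ads_percent=ads_percent,
        recovery_percent=recovery_percent,
        recovery_window_s=params.recovery_window_s,
    )


def compute_ads_metrics(
    trace: LatencyTrace, params: ClassificationParams | None = None
) -> ADSMetrics:
    """ADS metrics for a trace recorded under the rising-frequency protocol."""
    return compute_ads_metrics_from_arrays(
        trace.stimulus_times, trace.latencies, params
    )


def classify_fiber(
    metrics: ADSMetrics,
    mech: MechanicalProfile,
    params: ClassificationParams | None = None,
    *,
    fiber_id: str = "",
) -> FiberClassification:
    """Apply the CM/CMi/VHT decision rule (total over valid inputs)."""
    params = params or ClassificationParams()
    ads, rec = metrics.ads_percent, metrics.recovery_percent
    force = mech.lowest_responding_force_g

    label = "unclassifiable"
    if ads < params.ads_percent and rec > params.recovery_percent:
        if force is not None and force < params.cm_max_force_g:
            label = "CM"
    elif ads > params.ads_percent and rec < params.recovery_percent:
        if force is None:
            label = "CMi"
        elif force > params.vht_force_g:
            label = "VHT"
    return FiberClassification(
        fiber_id=fiber_id, class_label=label, metrics=metrics, mech=mech
    )


def classify_cohort(
    runs: Sequence[tuple[LatencyTrace, MechanicalProfile]],
    params: ClassificationParams | None = None,
) -> pd.DataFrame:
    """Classify every fiber of a cohort; one row per fiber.

    Columns: fiber_id, ads_percent, recovery_percent, mech_threshold_g,
    class_label.  Duplicate fiber ids are rejected.
    """
    params = params or ClassificationParams()
    seen: set[str] = set()
    rows = []
    for trace, mech in runs:
        if trace.fiber_id in seen:
            raise ValidationError(f"duplicate fiber_id {trace.fiber_id!r}")
        seen.add(trace.fiber_id)
        metrics = compute_ads_metrics(trace, params)
        cls = classify_fiber(metrics, mech, params, fiber_id=trace.fiber_id)
        rows.append(
            {
                "fiber_id": trace.fiber_id,
                "ads_percent": metrics.ads_percent,
                "recovery_percent": metrics.recovery_percent,
                "mech_threshold_g": mech.lowest_responding_force_g,
                "class_label": cls.class_label,
            }
        )
    columns = ["fiber_id", "ads_percent", "recovery_percent", "mech_threshold_g", "class_label"]
    return pd.DataFrame(rows, columns=columns)


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-class fiber counts (all labels present, zero-filled)."""
    counts = table["class_label"].value_counts().to_dict() if len(table) else {}
    return {label: int(counts.get(label, 0)) for label in CLASS_LABELS}


def mechanical_profile_for_threshold(threshold_g: Optional[float]) -> MechanicalProfile:
    """Profile whose lowest responding force is the nearest tested von Frey
    force at or above ``threshold_g`` (None = no response)."""
    if threshold_g is None:
        return MechanicalProfile()
    for force in VON_FREY_FORCES_G:
        if force >= threshold_g:
            return MechanicalProfile(lowest_responding_force_g=force)
    return MechanicalProfile()
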