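"""NRS psychophysics summaries: AUC, maxima, responders, erythema area.

Ratings are prompted values on a 10 s grid.  The default cumulative
measure (AUC) is the plain sum of samples (dimensionless NRS x samples);
a trapezoidal alternative over minutes is available.  A responder is a
subject who rates the sensation at or above the threshold (default 1) at
least once -- the 0.5 "neither itch nor pain" rating counts toward the
AUC but never toward responder status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from pruricode.types import RatingSeries, ValidationError


@dataclass(frozen=True)
class SeriesSummary:
    subject_id: str
    substance: str
    application_mode: str
    condition: str
    auc_itch: float
    auc_pain: float
    max_itch: float
    max_pain: float
    itch_responder: bool
    pain_responder: bool
    auc_method: str


@dataclass(frozen=True)
class ErythemaMeasurement:
    area_cm2: float
    widespread: bool  # area >= 1 cm^2


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = groups, columns = (responder, non-responder)."""

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("table counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _auc(values: Sequence[float], method: str, grid_s: float) -> float:
    arr = np.asarray(values, dtype=float)
    if method == "sum":
        return float(arr.sum())
    if method == "trapezoid":
        return float(np.trapezoid(arr, dx=grid_s / 60.0))  # NRS x minutes
    raise ValueError(f"unknown AUC method {method!r}")


def summarize_series(
    series: RatingSeries,
    responder_threshold: float = 1.0,
    auc_method: str = "sum",
) -> SeriesSummary:
    """Summarize one itch/pain rating series."""
    if not series.times_s:
        raise ValidationError("empty rating series")
    itch = np.asarray(series.itch)
    pain = np.asarray(series.pain)
    return SeriesSummary(
        subject_id=series.subject_id,
        substance=series.substance,
        application_mode=series.application_mode,
        condition=series.condition,
        auc_itch=_auc(itch, auc_method, series.grid_s),
        auc_pain=_auc(pain, auc_method, series.grid_s),
        max_itch=float(itch.max()),
        max_pain=float(pain.max()),
        itch_responder=bool(np.any(itch >= responder_threshold)),
        pain_responder=bool(np.any(pain >= responder_threshold)),
        auc_method=auc_method,
    )


def relevant_reduction(
    auc_condition: float,
    auc_control: float,
    delta: float = 5.0,
    *,
    method_condition: str = "sum",
    method_control: str = "sum",
) -> bool:
    """A reduction counts as relevant iff control - condition > delta
    (strictly more than 5 cumulative NRS points by default)."""
    if method_condition != method_control:
        raise ValidationError(
            "cannot compare AUCs computed with different methods "
            f"({method_condition!r} vs {method_control!r})"
        )
    return (auc_control - auc_condition) > delta


def responder_table(
    group_a: Sequence[SeriesSummary],
    group_b: Sequence[SeriesSummary],
    outcome: str = "itch",
    *,
    label: str = "",
) -> ContingencyTable2x2:
    """Build a 2x2 responder/non-responder table from two summary groups."""
    if outcome not in ("itch", "pain"):
        raise ValueError("outcome must be 'itch' or 'pain'")
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    attr = f"{outcome}_responder"
    counts = []
    for group in (group_a, group_b):
        subjects = [s.subject_id for s in group]
        if len(subjects) != len(set(subjects)):
            raise ValidationError("a subject appears twice within one group")
        n_resp = sum(getattr(s, attr) for s in group)
        counts.append((n_resp, len(group) - n_resp))
    (a, b), (c, d) = counts
    return ContingencyTable2x2(a=a, b=b, c=c, d=d, label=label)


def erythema_area(
    flux_image: np.ndarray,
    pixel_size_cm: tuple[float, float],
    flux_threshold: float,
    widespread_cm2: float = 1.0,
) -> ErythemaMeasurement:
    """Axon-reflex erythema area from a laser-Doppler flux image.

    Area = (number of pixels with flux strictly above threshold) x pixel
    area; the flare counts as widespread at or above ``widespread_cm2``
    (default 1 cm^2).
    """
    dy, dx = pixel_size_cm
    if dy <= 0 or dx <= 0:
        raise ValidationError("pixel size must be positive")
    image = np.asarray(flux_image, dtype=float)
    area = float(np.count_nonzero(image > flux_threshold) * dy * dx)
    return ErythemaMeasurement(area_cm2=area, widespread=area >= widespread_cm2)


def sine_wave_switch_table(
    pre_responders: Sequence[bool],
    post_responders: Sequence[bool],
    *,
    label: str = "sine_wave_switch",
) -> ContingencyTable2x2:
    """Pre/post itch-perceiver table for the same subject panel under
    electrical sine-wave stimulation (rows = pre, post)."""
    if len(pre_responders) != len(post_responders):
        raise ValidationError(
            f"panel size mismatch: {len(pre_responders)} pre vs "
            f"{len(post_responders)} post"
        )
    n = len(pre_responders)
    a = int(sum(bool(v) for v in pre_responders))
    c = int(sum(bool(v) for v in post_responders))
    return ContingencyTable2x2(a=a, b=n - a, c=c, d=n - c, label=label)
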