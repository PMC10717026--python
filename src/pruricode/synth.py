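"""Synthetic microneurography traces with exact ground truth.

The generator realizes the measurement premise of the marking technique
with a minimal first-order mechanism: a dimensionless slowing state S gains
a fixed increment per conducted action potential (electrical test pulse or
chemically evoked spike), decays exponentially with a class-specific time
constant, and saturates at a cap.  The latency recorded at stimulus i is

    latency_i = baseline * (1 + S(t_i)) + jitter,

evaluated just before the stimulus' own action potential, so a latency step
reflects exactly the discharge conducted since the previous test pulse.
Chemically evoked spikes are generated as explicit event times, never as
rates, so the per-interval ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from pruricode.types import (
    CLASSIFICATION_PROTOCOL,
    Event,
    EventLog,
    LatencyTrace,
    RatingSeries,
    StimulationProtocol,
    ValidationError,
)

TRACKING_DT_S = 4.0  # 0.25 Hz tracking


class ConfigurationError(ValueError):
    """Archetype parameters cannot satisfy their contract."""


@dataclass(frozen=True)
class FiberArchetypeParams:
    """Parameters of one simulated C-fiber class archetype.

    ``slowing_increment_per_ap`` is the fraction of baseline latency added
    to the slowing state per conducted action potential;
    ``mechanical_threshold_g`` is None for mechano-insensitive (CMi) fibers.
    """

    class_label: str  # CM | CMi | VHT
    baseline_latency_ms: float
    slowing_increment_per_ap: float
    recovery_time_constant_s: float
    slowing_saturation: float = 0.8
    latency_jitter_sd_ms: float = 0.1
    mechanical_threshold_g: Optional[float] = None
    conduction_distance_mm: float = 100.0

    def __post_init__(self) -> None:
        if self.slowing_increment_per_ap < 0:
            raise ValidationError("slowing_increment_per_ap must be >= 0")
        if self.recovery_time_constant_s <= 0:
            raise ValidationError("recovery_time_constant_s must be > 0")
        if self.latency_jitter_sd_ms < 0:
            raise ValidationError("latency jitter SD must be >= 0")
        if self.class_label == "CMi" and self.mechanical_threshold_g is not None:
            raise ValidationError("CMi archetypes carry no mechanical threshold")
        if self.class_label == "CM" and (
            self.mechanical_threshold_g is None or self.mechanical_threshold_g > 22
        ):
            raise ValidationError("CM archetypes must respond at <= 22 g")
        if self.class_label == "VHT" and (
            self.mechanical_threshold_g is None or self.mechanical_threshold_g <= 10
        ):
            raise ValidationError("VHT archetypes must respond only above 10 g")


#: Shipped archetypes.  Baseline latencies and conduction distances sit in
#: the recorded range (53-180 mm, CV < 2 m/s); slowing increments and
#: recovery time constants are chosen so the class criteria (ADS 5%,
#: recovery 24% within 40 s) separate the archetypes with margin, and so
#: that a single evoked spike shifts the next latency above the 0.5 ms
#: marking floor.
CM_ARCHETYPE = FiberArchetypeParams(
    class_label="CM",
    baseline_latency_ms=144.0,
    slowing_increment_per_ap=0.006,
    recovery_time_constant_s=10.0,
    mechanical_threshold_g=8.0,
    conduction_distance_mm=100.0,
)
CMI_ARCHETYPE = FiberArchetypeParams(
    class_label="CMi",
    baseline_latency_ms=288.0,
    slowing_increment_per_ap=0.004,
    recovery_time_constant_s=150.0,
    mechanical_threshold_g=None,
    conduction_distance_mm=120.0,
)
VHT_ARCHETYPE = FiberArchetypeParams(
    class_label="VHT",
    baseline_latency_ms=250.0,
    slowing_increment_per_ap=0.0045,
    recovery_time_constant_s=130.0,
    mechanical_threshold_g=15.0,
    conduction_distance_mm=110.0,
)
ARCHETYPES = {"CM": CM_ARCHETYPE, "CMi": CMI_ARCHETYPE, "VHT": VHT_ARCHETYPE}


@dataclass(frozen=True)
class ChemicalStimulusProfile:
    """Chemically evoked discharge: none, tonic (decaying rate) or bursting.

    Tonic discharge is an inhomogeneous Poisson process with rate
    ``rate0 * exp(-(t - onset)/rate_decay_s)``; bursting discharge places
    ``n_bursts`` trains of ``aps_per_burst`` spikes, each train lasting at
    most ``burst_duration_s`` (<= 4 s) and separated by at least
    ``inter_burst_gap_s`` (>= 20 s).  With ``align_to_grid`` (the default)
    each burst starts just after a tracked stimulus so the whole train
    falls into a single inter-stimulus interval.
    """

    mode: str = "none"  # none | tonic | bursting
    onset_s: float = 0.0
    rate0_aps_per_s: float = 2.0
    rate_decay_s: float = 300.0
    duration_s: float = 300.0
    dispersion: str = "poisson"  # poisson | regular (deterministic rate)
    n_bursts: int = 3
    aps_per_burst: int = 20
    burst_duration_s: float = 3.0
    inter_burst_gap_s: float = 30.0
    align_to_grid: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("none", "tonic", "bursting"):
            raise ValidationError(f"unknown chemical mode {self.mode!r}")
        if self.dispersion not in ("poisson", "regular"):
            raise ValidationError(f"unknown dispersion {self.dispersion!r}")
        if self.mode == "bursting":
            if self.burst_duration_s > 4.0:
                raise ValidationError("burst_duration_s must be <= 4 s")
            if self.inter_burst_gap_s < 20.0:
                raise ValidationError("inter_burst_gap_s must be >= 20 s")


@dataclass
class GroundTruth:
    """Chemically evoked spike times plus per-stimulus interval counts."""

    evoked_ap_times: np.ndarray  # s
    interval_counts: np.ndarray  # APs in (t_{i-1}, t_i] per stimulus
    is_bursting: bool
    is_activated: bool
    n_bursts: int = 0


def _chemical_ap_times(
    chem: ChemicalStimulusProfile,
    stimulus_times: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Generate evoked spike times; returns (times, number of bursts)."""
    t_last = stimulus_times[-1]
    if chem.mode == "none":
        return np.empty(0), 0
    if chem.mode == "tonic":
        t_end = min(chem.onset_s + chem.duration_s, t_last)
        if chem.dispersion == "regular":
            # deterministic train: per inter-stimulus interval, a rounded
            # count from the decaying envelope, spikes evenly spaced.
            # Rounding a monotone envelope keeps per-interval counts
            # non-increasing over time.
            times_reg: list[float] = []
            for lo, hi in zip(stimulus_times[:-1], stimulus_times[1:]):
                if hi <= chem.onset_s or lo >= t_end:
                    continue
                a, b = max(lo, chem.onset_s), min(hi, t_end)
                mid = 0.5 * (a + b)
                rate = chem.rate0_aps_per_s * np.exp(
                    -(mid - chem.onset_s) / chem.rate_decay_s
                )
                k = int(round(rate * (b - a)))
                if k > 0:
                    times_reg.extend(np.linspace(a, b, k + 2)[1:-1])
            return np.asarray(times_reg), 0
        # Poisson thinning against the initial rate
        times = []
        t = chem.onset_s
        while t < t_end:
            t += rng.exponential(1.0 / chem.rate0_aps_per_s)
            if t >= t_end:
                break
            rate = chem.rate0_aps_per_s * np.exp(-(t - chem.onset_s) / chem.rate_decay_s)
            if rng.uniform() < rate / chem.rate0_aps_per_s:
                times.append(t)
        return np.asarray(times), 0
    # bursting: deterministic evenly spaced spikes inside each train
    times = []
    start = chem.onset_s
    n_placed = 0
    for _ in range(chem.n_bursts):
        if chem.align_to_grid:
            later = stimulus_times[stimulus_times >= start]
            if not len(later):
                break
            start = float(later[0]) + 0.05
        if start + chem.burst_duration_s > t_last:
            break
        offsets = np.linspace(0.0, chem.burst_duration_s * 0.95, chem.aps_per_burst)
        times.extend(start + offsets)
        n_placed += 1
        start = start + chem.burst_duration_s + chem.inter_burst_gap_s
    return np.asarray(times), n_placed


def _interval_counts(stimulus_times: np.ndarray, ap_times: np.ndarray) -> np.ndarray:
    """APs in the inter-stimulus interval (t_{i-1}, t_i] preceding each stimulus."""
    counts = np.zeros(len(stimulus_times), dtype=int)
    if not len(ap_times):
        return counts
    idx = np.searchsorted(stimulus_times, ap_times, side="left")
    for j in idx:
        if j < len(counts):
            counts[j] += 1
    return counts


def simulate_trace(
    archetype: FiberArchetypeParams,
    protocol: StimulationProtocol,
    chem: ChemicalStimulusProfile,
    events: EventLog,
    seed: int,
    *,
    fiber_id: str = "fiber",
    duration_s: Optional[float] = None,
) -> tuple[LatencyTrace, GroundTruth]:
    """Simulate one chemically stimulated tracking run.

    The fiber is tracked at ``protocol.tracking_frequency_hz`` for
    ``duration_s`` (default: until 360 s after chemical onset).  ``seed``
    is mandatory: all randomness flows through it.
    """
    if seed is None:
        raise ValidationError("a seed is required; simulations must be reproducible")
    if chem.mode != "none" and chem.onset_s < 0:
        raise ValidationError("chemical onset before recording start")
    rng = np.random.default_rng(seed)

    dt = 1.0 / protocol.tracking_frequency_hz
    if duration_s is None:
        duration_s = (chem.onset_s if chem.mode != "none" else 0.0) + 360.0
    n_stimuli = int(np.floor(duration_s / dt)) + 1
    stimulus_times = np.arange(n_stimuli) * dt

    ap_times, n_bursts = _chemical_ap_times(chem, stimulus_times, rng)
    latencies = _ads_latencies(
        archetype, stimulus_times, ap_times, rng, equilibrated=True
    )

    trace = LatencyTrace(
        fiber_id=fiber_id,
        stimulus_times=stimulus_times,
        latencies=latencies,
        conduction_distance_mm=archetype.conduction_distance_mm,
        events=events,
        protocol=protocol,
    )
    truth = GroundTruth(
        evoked_ap_times=ap_times,
        interval_counts=_interval_counts(stimulus_times, ap_times),
        is_bursting=chem.mode == "bursting" and n_bursts >= 3,
        is_activated=chem.mode != "none" and len(ap_times) > 0,
        n_bursts=n_bursts,
    )
    return trace, truth


def _ads_latencies(
    archetype: FiberArchetypeParams,
    stimulus_times: np.ndarray,
    chemical_ap_times: np.ndarray,
    rng: np.random.Generator,
    *,
    equilibrated: bool = False,
) -> np.ndarray:
    """Latency at each stimulus from the first-order slowing state.

    Events are processed in time order; electrical action potentials are
    read out (latency = baseline * (1 + S)) *before* their own increment is
    applied, so the marking at stimulus i reflects only discharge before
    t_i.  Chemical spikes at exactly a stimulus time count for the next
    interval.

    ``equilibrated`` starts S at the steady state of continuous tracking
    (a recorded fiber has been tracked long before any application), so the
    pre-application baseline is flat; classification runs instead start
    from rest.
    """
    eps = archetype.slowing_increment_per_ap
    tau = archetype.recovery_time_constant_s
    cap = archetype.slowing_saturation
    base = archetype.baseline_latency_ms

    # merge: (time, kind) with electrical events ordered before chemical
    # ones at identical times
    ev_t = np.concatenate([stimulus_times, chemical_ap_times])
    ev_kind = np.concatenate(
        [np.zeros(len(stimulus_times), dtype=int), np.ones(len(chemical_ap_times), dtype=int)]
    )
    order = np.lexsort((ev_kind, ev_t))

    latencies = np.empty(len(stimulus_times))
    s = 0.0
    if equilibrated and len(stimulus_times) > 1:
        # fixed point of s -> (s + eps) * exp(-dt/tau) under pure tracking
        dt = float(stimulus_times[1] - stimulus_times[0])
        decay = np.exp(-dt / tau)
        s = min(eps * decay / (1.0 - decay), cap)
    t_prev = stimulus_times[0] if len(stimulus_times) else 0.0
    stim_seen = 0
    for k in order:
        t = ev_t[k]
        s *= np.exp(-(t - t_prev) / tau)
        t_prev = t
        if ev_kind[k] == 0:
            latencies[stim_seen] = base * (1.0 + s)
            stim_seen += 1
        s = min(s + eps, cap)
    if archetype.latency_jitter_sd_ms > 0:
        latencies = latencies + rng.normal(
            0.0, archetype.latency_jitter_sd_ms, size=len(latencies)
        )
    return latencies


def simulate_classification_run(
    archetype: FiberArchetypeParams,
    seed: int,
    *,
    post_tracking_s: float = 48.0,
    fiber_id: str = "fiber",
) -> LatencyTrace:
    """Simulate the rising-frequency ADS protocol (20 @ 0.125 Hz, 20 @
    0.25 Hz, 30 @ 0.5 Hz) followed by tracking at 0.25 Hz.

    Raises :class:`ConfigurationError` if the archetype, run noise-free,
    does not land in its own classification region.
    """
    if seed is None:
        raise ValidationError("a seed is required; simulations must be reproducible")
    n_tracking = int(post_tracking_s * 0.25) + 1
    stimulus_times = CLASSIFICATION_PROTOCOL.stimulus_times(n_tracking=n_tracking)

    noise_free = replace(archetype, latency_jitter_sd_ms=0.0)
    clean = _ads_latencies(noise_free, stimulus_times, np.empty(0), np.random.default_rng(0))
    _verify_class_region(archetype, stimulus_times, clean)

    rng = np.random.default_rng(seed)
    latencies = _ads_latencies(archetype, stimulus_times, np.empty(0), rng)
    return LatencyTrace(
        fiber_id=fiber_id,
        stimulus_times=stimulus_times,
        latencies=latencies,
        conduction_distance_mm=archetype.conduction_distance_mm,
        protocol=CLASSIFICATION_PROTOCOL,
    )


def _verify_class_region(
    archetype: FiberArchetypeParams,
    stimulus_times: np.ndarray,
    clean_latencies: np.ndarray,
) -> None:
    from pruricode.classification import compute_ads_metrics_from_arrays

    metrics = compute_ads_metrics_from_arrays(stimulus_times, clean_latencies)
    label = archetype.class_label
    if label == "CM":
        ok = metrics.ads_percent < 5.0 and metrics.recovery_percent > 24.0
    else:
        ok = metrics.ads_percent > 5.0 and metrics.recovery_percent < 24.0
    if not ok:
        raise ConfigurationError(
            f"{label} archetype falls outside its class region at zero jitter "
            f"(ADS {metrics.ads_percent:.2f}%, recovery {metrics.recovery_percent:.2f}%)"
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Per-substance activation probability by fiber class and bursting
#: probability among activated CM-fibers; values mirror the observed
#: activation fractions of the study cohort.
DEFAULT_SUBSTANCES: dict[str, dict] = {
    "beta_alanine": {
        "activation": {"CM": 1.0, "CMi": 0.10, "VHT": 6 / 7},
        "bursting_cm": 10 / 34,
    },
    "bam8_22": {
        "activation": {"CM": 34 / 38, "CMi": 0.0, "VHT": 1.0},
        "bursting_cm": 12 / 34,
    },
    "cowhage": {
        "activation": {"CM": 10 / 18, "CMi": 0.25, "VHT": 0.0},
        "bursting_cm": 0.20,
    },
}

#: Study-scale class composition: 50 CM, 14 CMi, 7 VHT fibers.
DEFAULT_CLASS_COUNTS = {"CM": 50, "CMi": 14, "VHT": 7}

#: Responder probabilities for synthetic NRS cohorts (itch, pain) by
#: substance and application mode, mirroring the reported responder counts.
DEFAULT_RATING_PROFILES: dict[tuple[str, str], dict] = {
    ("beta_alanine", "injection"): {"p_itch": 20 / 24, "p_pain": 17 / 24, "peak_itch": 2.6, "peak_pain": 1.5},
    ("beta_alanine", "focal"): {"p_itch": 18 / 24, "p_pain": 11 / 24, "peak_itch": 1.3, "peak_pain": 0.7},
    ("bam8_22", "injection"): {"p_itch": 18 / 22, "p_pain": 14 / 22, "peak_itch": 2.1, "peak_pain": 1.4},
    ("bam8_22", "focal"): {"p_itch": 18 / 22, "p_pain": 8 / 22, "peak_itch": 2.4, "peak_pain": 0.7},
    ("cowhage", "injection"): {"p_itch": 18 / 24, "p_pain": 19 / 24, "peak_itch": 2.9, "peak_pain": 2.1},
    ("cowhage", "focal"): {"p_itch": 21 / 24, "p_pain": 11 / 24, "peak_itch": 2.7, "peak_pain": 1.0},
}

NRS_GRID = np.array([0.0, 0.5] + list(range(1, 11)))


@dataclass
class CohortConfig:
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    substances: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBSTANCES.items()})
    rating_profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RATING_PROFILES.items()})
    n_subjects: int = 24
    rating_duration_s: float = 360.0
    injection_t_start_s: float = 120.0
    injection_duration_s: float = 20.0
    jitter_sd_ms: Optional[float] = None  # None = archetype default


@dataclass
class CohortDataset:
    traces: list  # (trace, truth, class_label, substance)
    classification_runs: list  # (trace, class_label, mech_threshold_g)
    ratings: list  # RatingSeries
    seed: int


def _chem_profile_for(
    activated: bool, bursting: bool, onset_s: float, rng: np.random.Generator
) -> ChemicalStimulusProfile:
    if not activated:
        return ChemicalStimulusProfile(mode="none")
    if bursting:
        return ChemicalStimulusProfile(
            mode="bursting",
            onset_s=onset_s,
            n_bursts=int(rng.integers(3, 6)),
            aps_per_burst=int(rng.integers(12, 30)),
            burst_duration_s=3.0,
            inter_burst_gap_s=float(rng.uniform(24.0, 60.0)),
        )
    return ChemicalStimulusProfile(
        mode="tonic",
        onset_s=onset_s,
        rate0_aps_per_s=float(rng.uniform(1.5, 3.0)),
        rate_decay_s=300.0,
        duration_s=300.0,
    )


def _gamma_shape(times: np.ndarray, peak: float, t_peak: float = 90.0) -> np.ndarray:
    x = np.clip(times, 0.0, None) / t_peak
    return peak * x * np.exp(1.0 - x)


def _snap_to_nrs(values: np.ndarray) -> np.ndarray:
    idx = np.abs(values[:, None] - NRS_GRID[None, :]).argmin(axis=1)
    return NRS_GRID[idx]


def generate_cohort(config: CohortConfig, seed: int) -> CohortDataset:
    """Generate a full synthetic cohort: chemically stimulated traces with
    ground truth, classification runs, and matched NRS rating series.

    Same (config, seed) always yields an identical dataset.
    """
    if seed is None:
        raise ValidationError("a seed is required; simulations must be reproducible")
    rng = np.random.default_rng(seed)
    total = sum(config.class_counts.values())
    if total == 0:
        import warnings

        warnings.warn("empty cohort requested", stacklevel=2)

    protocol = StimulationProtocol()
    injection = Event(
        kind="injection",
        t_start=config.injection_t_start_s,
        t_end=config.injection_t_start_s + config.injection_duration_s,
    )
    events = EventLog(entries=(injection,))

    traces = []
    classification_runs = []
    fiber_no = 0
    for label, count in config.class_counts.items():
        base = ARCHETYPES[label]
        if config.jitter_sd_ms is not None:
            base = replace(base, latency_jitter_sd_ms=config.jitter_sd_ms)
        for _ in range(count):
            fiber_no += 1
            fiber_id = f"{label}-{fiber_no:03d}"
            cls_seed = int(rng.integers(0, 2**31 - 1))
            run = simulate_classification_run(base, cls_seed, fiber_id=fiber_id)
            classification_runs.append((run, label, base.mechanical_threshold_g))
            for substance, spec in config.substances.items():
                p_act = spec["activation"].get(label, 0.0)
                activated = bool(rng.uniform() < p_act)
                bursting = bool(
                    activated and label == "CM" and rng.uniform() < spec.get("bursting_cm", 0.0)
                )
                chem = _chem_profile_for(
                    activated, bursting, injection.t_end + 2.0, rng
                )
                trace_seed = int(rng.integers(0, 2**31 - 1))
                trace, truth = simulate_trace(
                    base,
                    protocol,
                    chem,
                    events,
                    trace_seed,
                    fiber_id=fiber_id,
                    duration_s=injection.t_end + 340.0,
                )
                traces.append((trace, truth, label, substance))

    ratings = _generate_ratings(config, rng)
    return CohortDataset(
        traces=traces,
        classification_runs=classification_runs,
        ratings=ratings,
        seed=seed,
    )


def _generate_ratings(config: CohortConfig, rng: np.random.Generator) -> list[RatingSeries]:
    times = np.arange(0.0, config.rating_duration_s, 10.0)
    out: list[RatingSeries] = []
    for (substance, mode), prof in config.rating_profiles.items():
        for subj in range(config.n_subjects):
            row = {}
            for sensation, p_key, peak_key in (
                ("itch", "p_itch", "peak_itch"),
                ("pain", "p_pain", "peak_pain"),
            ):
                responder = rng.uniform() < prof[p_key]
                if responder:
                    peak = max(1.0, rng.normal(prof[peak_key], 0.6))
                else:
                    peak = float(rng.choice([0.0, 0.5]))
                curve = _gamma_shape(times, peak)
                noisy = curve + rng.normal(0.0, 0.15, size=len(times))
                snapped = _snap_to_nrs(np.clip(noisy, 0.0, 10.0))
                if responder and snapped.max() < 1.0:
                    snapped[int(np.argmax(curve))] = max(1.0, round(peak))
                if not responder:
                    snapped = np.minimum(snapped, 0.5)
                row[sensation] = tuple(float(v) for v in snapped)
            out.append(
                RatingSeries(
                    subject_id=f"S{subj + 1:02d}",
                    substance=substance,
                    application_mode=mode,
                    times_s=tuple(float(t) for t in times),
                    itch=row["itch"],
                    pain=row["pain"],
                )
            )
    return out
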