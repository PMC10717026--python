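"""Activation-period detection, cumulative latency, bursting pattern."""

import numpy as np
import pytest

from conftest import (
    CHEM_ONSET_S,
    INJECTION_END_S,
    bursting_profile,
    tonic_profile,
)
from pruricode import marking
from pruricode.config import BurstingParams, MarkingThresholdPolicy
from pruricode.marking import (
    ActivationPeriod,
    AnalysisError,
    activation_percentage,
    activation_table,
    detect_activation_periods,
    detect_slow_bursting,
    summarize_chemical_response,
)
from pruricode.synth import ChemicalStimulusProfile
from pruricode.types import Event, EventLog, LatencyTrace, ValidationError


def make_trace(latencies, events=None, distance=150.0):
    latencies = np.asarray(latencies, dtype=float)
    return LatencyTrace(
        fiber_id="t",
        stimulus_times=np.arange(len(latencies)) * 4.0,
        latencies=latencies,
        conduction_distance_mm=distance,
        events=events or EventLog(),
    )


class TestDetectActivationPeriods:
    def test_constant_trace_empty(self):
        trace = make_trace([150.0] * 60)
        assert detect_activation_periods(trace, window=(100.0, 200.0)) == []

    def test_explicit_steps_detected(self):
        lat = [150.0] * 30 + [158.0] + [157.0] * 29
        trace = make_trace(lat)
        periods = detect_activation_periods(trace, window=(100.0, 240.0))
        assert [p.stimulus_index for p in periods] == [30]
        assert periods[0].latency_shift_ms == pytest.approx(8.0)

    def test_gap_breaks_adjacency(self):
        lat = [150.0] * 30 + [np.nan, 158.0] + [157.0] * 28
        trace = make_trace(lat)
        # the 8 ms step lands after a conduction failure: not comparable
        assert detect_activation_periods(trace, window=(100.0, 240.0)) == []

    def test_window_from_event_log(self, noise_free_archetypes, simulate_chemical_run):
        trace, truth = simulate_chemical_run(
            noise_free_archetypes["CM"], bursting_profile(), seed=3
        )
        periods = detect_activation_periods(trace)
        expected = {
            i
            for i, c in enumerate(truth.interval_counts)
            if c > 0 and trace.stimulus_times[i] >= INJECTION_END_S
        }
        assert {p.stimulus_index for p in periods} == expected

    def test_needle_window_shifts_not_counted(self, noise_free_archetypes, simulate_chemical_run):
        """Markings during needle-in time are excluded from the analysis."""
        chem = ChemicalStimulusProfile(
            mode="bursting",
            onset_s=122.0,  # inside the injection window 120-140 s
            n_bursts=1,
            aps_per_burst=20,
            burst_duration_s=3.0,
            inter_burst_gap_s=30.0,
        )
        trace, truth = simulate_chemical_run(noise_free_archetypes["CM"], chem, seed=3)
        assert truth.interval_counts.sum() == 20  # the discharge did happen
        assert detect_activation_periods(trace) == []

    def test_missing_baseline_errors(self):
        trace = make_trace([150.0] * 10)
        with pytest.raises(AnalysisError, match="pre-application"):
            detect_activation_periods(trace, window=(20.0, 40.0))

    def test_threshold_monotonicity(self, noise_free_archetypes, simulate_chemical_run):
        """Raising the floor never yields more periods or more cumulative shift."""
        trace, _ = simulate_chemical_run(
            noise_free_archetypes["CM"], tonic_profile("poisson"), seed=11
        )
        prev_n, prev_cum = np.inf, np.inf
        for floor in (0.5, 1.0, 2.0, 5.0):
            policy = MarkingThresholdPolicy(absolute_floor_ms=floor)
            periods = detect_activation_periods(trace, policy)
            summary = summarize_chemical_response(periods)
            assert summary.n_activation_periods <= prev_n
            assert summary.cumulative_latency_ms <= prev_cum + 1e-12
            prev_n, prev_cum = summary.n_activation_periods, summary.cumulative_latency_ms


class TestSummarizeChemicalResponse:
    def test_empty(self):
        s = summarize_chemical_response([])
        assert (s.n_activation_periods, s.cumulative_latency_ms, s.activated) == (0, 0.0, False)

    def test_exactly_five_ms_is_not_activated(self):
        periods = [ActivationPeriod(1, 4.0, 2.0), ActivationPeriod(2, 8.0, 3.0)]
        s = summarize_chemical_response(periods)
        assert s.cumulative_latency_ms == pytest.approx(5.0)
        assert s.activated is False  # criterion is strictly 'exceeds 5 ms'

    def test_above_criterion_activated(self):
        periods = [
            ActivationPeriod(1, 4.0, 2.0),
            ActivationPeriod(2, 8.0, 3.0),
            ActivationPeriod(3, 12.0, 0.6),
        ]
        s = summarize_chemical_response(periods)
        assert s.cumulative_latency_ms == pytest.approx(5.6)
        assert s.activated is True

    def test_negative_shift_rejected(self):
        with pytest.raises(ValidationError):
            summarize_chemical_response([ActivationPeriod(1, 4.0, -0.5)])

    def test_cumulative_invariant_under_split(self, noise_free_archetypes, simulate_chemical_run):
        """Summing piecewise over sub-windows split at silent stimuli equals
        the whole-window cumulative latency."""
        trace, _ = simulate_chemical_run(
            noise_free_archetypes["CM"], bursting_profile(n_bursts=4), seed=13
        )
        whole = detect_activation_periods(trace, window=(INJECTION_END_S, 440.0))
        total = summarize_chemical_response(whole).cumulative_latency_ms
        split_at = 300.0  # a silent time between bursts
        left = detect_activation_periods(trace, window=(INJECTION_END_S, split_at))
        right = detect_activation_periods(trace, window=(split_at + 0.1, 440.0))
        parts = (
            summarize_chemical_response(left).cumulative_latency_ms
            + summarize_chemical_response(right).cumulative_latency_ms
        )
        assert parts == pytest.approx(total)


class TestSlowBursting:
    def test_three_bursts_detected(self, noise_free_archetypes, simulate_chemical_run):
        trace, truth = simulate_chemical_run(
            noise_free_archetypes["CM"], bursting_profile(n_bursts=3), seed=5
        )
        periods = detect_activation_periods(trace)
        res = detect_slow_bursting(trace, periods)
        assert res.is_bursting is True
        assert len(res.bursts) == truth.n_bursts == 3
        assert all(b.silence_duration_s >= 20.0 for b in res.bursts)

    def test_two_bursts_not_bursting(self, noise_free_archetypes, simulate_chemical_run):
        trace, _ = simulate_chemical_run(
            noise_free_archetypes["CM"], bursting_profile(n_bursts=2), seed=5
        )
        periods = detect_activation_periods(trace)
        res = detect_slow_bursting(trace, periods)
        assert res.is_bursting is False
        assert len(res.bursts) == 2  # at least three repetitions required

    def test_tonic_not_bursting(self, noise_free_archetypes, simulate_chemical_run):
        for label in ("CM", "CMi", "VHT"):
            trace, _ = simulate_chemical_run(
                noise_free_archetypes[label], tonic_profile("regular"), seed=5
            )
            periods = detect_activation_periods(trace)
            assert detect_slow_bursting(trace, periods).is_bursting is False

    def test_wrong_tracking_frequency_refused(self):
        lat = np.full(80, 150.0)
        trace = LatencyTrace(
            fiber_id="t",
            stimulus_times=np.arange(80) * 2.0,  # 0.5 Hz
            latencies=lat,
            conduction_distance_mm=150.0,
        )
        with pytest.raises(AnalysisError, match="0.25 Hz"):
            detect_slow_bursting(trace, [], window_start=100.0)

    def test_failure_inside_silent_run_invalidates(self):
        lat = [150.0] * 30 + [158.0] + [154.0, 153.0, np.nan, 152.0, 151.5] + [151.0] * 10
        trace = make_trace(lat)
        periods = detect_activation_periods(trace, window=(100.0, 184.0))
        assert [p.stimulus_index for p in periods] == [30]
        res = detect_slow_bursting(trace, periods, window_start=100.0)
        assert res.bursts == ()


class TestActivationTable:
    def test_printed_percentages(self):
        assert activation_percentage(10, 18) == 55.6
        assert activation_percentage(10, 18, decimals=0) == 56
        assert activation_percentage(34, 38) == 89.5
        assert activation_percentage(0, 12) == 0.0

    def test_aggregation(self):
        records = [
            {"class_label": "CM", "substance": "cowhage", "activated": i < 10, "bursting": i < 2}
            for i in range(18)
        ]
        table = activation_table(records)
        row = table.iloc[0]
        assert (row.n_tested, row.n_activated, row.pct_activated) == (18, 10, 55.6)
        assert (row.n_bursting, row.pct_bursting) == (2, 11.1)

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValidationError, match="substance"):
            activation_table([{"class_label": "CM", "activated": True, "bursting": False}])
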