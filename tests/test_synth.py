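"""Generator contracts: determinism, slowing monotonicity, ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import CHEM_ONSET_S, bursting_profile, tonic_profile
from pruricode.classification import (
    class_counts,
    classify_cohort,
    mechanical_profile_for_threshold,
)
from pruricode.synth import (
    ARCHETYPES,
    CM_ARCHETYPE,
    ChemicalStimulusProfile,
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    simulate_classification_run,
    simulate_trace,
)
from pruricode.types import ValidationError


class TestSimulateTrace:
    def test_no_chemistry_zero_jitter_is_flat(self, noise_free_archetypes, simulate_chemical_run):
        trace, truth = simulate_chemical_run(
            noise_free_archetypes["CM"], ChemicalStimulusProfile(mode="none"), seed=1
        )
        # pre-equilibrated tracking: latency is constant at the plateau
        assert np.ptp(trace.latencies) == pytest.approx(0.0, abs=1e-9)
        assert truth.is_activated is False
        assert len(truth.evoked_ap_times) == 0

    def test_fast_recovery_limit_returns_baseline(self, simulate_chemical_run):
        arch = replace(
            CM_ARCHETYPE, recovery_time_constant_s=1e-6, latency_jitter_sd_ms=0.0
        )
        trace, _ = simulate_chemical_run(arch, bursting_profile(), seed=1)
        assert np.allclose(trace.latencies, arch.baseline_latency_ms, atol=1e-6)

    def test_determinism(self, noise_free_archetypes, simulate_chemical_run):
        a = simulate_chemical_run(ARCHETYPES["CM"], tonic_profile("poisson"), seed=42)
        b = simulate_chemical_run(ARCHETYPES["CM"], tonic_profile("poisson"), seed=42)
        assert np.array_equal(a[0].latencies, b[0].latencies)
        assert np.array_equal(a[1].evoked_ap_times, b[1].evoked_ap_times)

    def test_seed_required(self, tracking_protocol, injection_events):
        with pytest.raises(ValidationError, match="seed"):
            simulate_trace(
                CM_ARCHETYPE,
                tracking_protocol,
                ChemicalStimulusProfile(mode="none"),
                injection_events,
                seed=None,
            )

    def test_negative_onset_rejected(self, tracking_protocol, injection_events):
        with pytest.raises(ValidationError, match="onset"):
            simulate_trace(
                CM_ARCHETYPE,
                tracking_protocol,
                ChemicalStimulusProfile(mode="tonic", onset_s=-5.0),
                injection_events,
                seed=1,
            )

    def test_ground_truth_count_conservation(self, noise_free_archetypes, simulate_chemical_run):
        for profile in (bursting_profile(n_bursts=4), tonic_profile("poisson")):
            _, truth = simulate_chemical_run(noise_free_archetypes["CMi"], profile, seed=3)
            assert truth.interval_counts.sum() == len(truth.evoked_ap_times)

    def test_slowing_monotone_in_discharge(self, noise_free_archetypes, simulate_chemical_run):
        """Adding evoked spikes to an interval never decreases the next latency."""
        arch = noise_free_archetypes["CM"]
        small = bursting_profile(n_bursts=3, aps_per_burst=5)
        large = bursting_profile(n_bursts=3, aps_per_burst=25)
        t_small, _ = simulate_chemical_run(arch, small, seed=1)
        t_large, _ = simulate_chemical_run(arch, large, seed=1)
        assert np.all(t_large.latencies >= t_small.latencies - 1e-12)

    def test_burst_count_scales_shift(self, noise_free_archetypes, simulate_chemical_run):
        """The marking magnitude grows with the preceding interval's spike count."""
        arch = noise_free_archetypes["CM"]
        shifts = []
        for aps in (5, 10, 20):
            trace, truth = simulate_chemical_run(
                arch, bursting_profile(n_bursts=1, aps_per_burst=aps), seed=1
            )
            idx = int(np.nonzero(truth.interval_counts)[0][0])
            shifts.append(trace.latencies[idx] - trace.latencies[idx - 1])
        assert shifts[0] < shifts[1] < shifts[2]


class TestClassificationRun:
    def test_zero_increment_gives_zero_ads(self):
        from pruricode.classification import compute_ads_metrics

        arch = replace(
            CM_ARCHETYPE, slowing_increment_per_ap=0.0, latency_jitter_sd_ms=0.0
        )
        # zero ADS also means zero recovery: outside every class region
        with pytest.raises(ConfigurationError):
            simulate_classification_run(arch, seed=1)

    def test_misparameterized_archetype_refused(self):
        bad = replace(CM_ARCHETYPE, recovery_time_constant_s=500.0)
        with pytest.raises(ConfigurationError, match="class region"):
            simulate_classification_run(bad, seed=1)

    @pytest.mark.parametrize("label", ["CM", "CMi", "VHT"])
    def test_shipped_archetypes_recovered(self, label, noise_free_archetypes):
        from pruricode.classification import classify_fiber, compute_ads_metrics

        arch = noise_free_archetypes[label]
        trace = simulate_classification_run(arch, seed=7)
        metrics = compute_ads_metrics(trace)
        mech = mechanical_profile_for_threshold(arch.mechanical_threshold_g)
        assert classify_fiber(metrics, mech).class_label == label


class TestCohort:
    def test_default_counts_and_determinism(self):
        config = CohortConfig(jitter_sd_ms=0.0)
        d1 = generate_cohort(config, seed=5)
        d2 = generate_cohort(config, seed=5)
        assert len(d1.classification_runs) == 71  # 50 CM + 14 CMi + 7 VHT
        assert len(d1.traces) == 71 * 3
        for (ta, _, _, _), (tb, _, _, _) in zip(d1.traces, d2.traces):
            assert np.array_equal(ta.latencies, tb.latencies)

    def test_cohort_classification_recovery_zero_jitter(self):
        config = CohortConfig(jitter_sd_ms=0.0)
        dataset = generate_cohort(config, seed=5)
        runs = [
            (trace, mechanical_profile_for_threshold(thr))
            for trace, _, thr in dataset.classification_runs
        ]
        counts = class_counts(classify_cohort(runs))
        assert counts == {"CM": 50, "CMi": 14, "VHT": 7, "unclassifiable": 0}

    def test_zero_probability_means_no_activation(self):
        """A class with activation probability 0 gets only 'none' profiles."""
        config = CohortConfig(
            class_counts={"CMi": 8},
            substances={"bam8_22": {"activation": {"CMi": 0.0}, "bursting_cm": 0.0}},
            jitter_sd_ms=0.0,
        )
        dataset = generate_cohort(config, seed=2)
        assert all(not truth.is_activated for _, truth, _, _ in dataset.traces)

    def test_empty_cohort_warns(self):
        config = CohortConfig(class_counts={}, substances={})
        with pytest.warns(UserWarning, match="empty cohort"):
            dataset = generate_cohort(config, seed=1)
        assert dataset.traces == []

    def test_ratings_on_grid(self):
        dataset = generate_cohort(CohortConfig(), seed=9)
        assert dataset.ratings, "default cohort must include rating series"
        for s in dataset.ratings[:10]:
            assert s.grid_s == 10.0
            assert all(v in s.ALLOWED_RATINGS for v in s.itch + s.pain)
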