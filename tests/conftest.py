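"""Shared fixtures: noise-free archetypes, standard event logs, profiles."""

from dataclasses import replace

import pytest

from pruricode.synth import (
    ARCHETYPES,
    ChemicalStimulusProfile,
    simulate_trace,
)
from pruricode.types import Event, EventLog, StimulationProtocol

INJECTION_START_S = 120.0
INJECTION_END_S = 140.0
CHEM_ONSET_S = 142.0
TRACE_DURATION_S = 460.0


@pytest.fixture
def tracking_protocol() -> StimulationProtocol:
    return StimulationProtocol()


@pytest.fixture
def injection_events() -> EventLog:
    return EventLog(entries=(Event("injection", INJECTION_START_S, INJECTION_END_S),))


@pytest.fixture
def noise_free_archetypes() -> dict:
    return {
        label: replace(arch, latency_jitter_sd_ms=0.0)
        for label, arch in ARCHETYPES.items()
    }


@pytest.fixture
def simulate_chemical_run(tracking_protocol, injection_events):
    """Factory: simulate one chemically stimulated tracking run with the
    standard injection timing."""

    def _run(archetype, chem: ChemicalStimulusProfile, seed: int):
        return simulate_trace(
            archetype,
            tracking_protocol,
            chem,
            injection_events,
            seed,
            duration_s=TRACE_DURATION_S,
        )

    return _run


def bursting_profile(n_bursts=3, aps_per_burst=20, gap_s=30.0, onset_s=CHEM_ONSET_S):
    return ChemicalStimulusProfile(
        mode="bursting",
        onset_s=onset_s,
        n_bursts=n_bursts,
        aps_per_burst=aps_per_burst,
        burst_duration_s=3.0,
        inter_burst_gap_s=gap_s,
    )


def tonic_profile(dispersion="regular", rate0=2.0, onset_s=CHEM_ONSET_S):
    return ChemicalStimulusProfile(
        mode="tonic",
        onset_s=onset_s,
        rate0_aps_per_s=rate0,
        rate_decay_s=300.0,
        duration_s=320.0,
        dispersion=dispersion,
    )
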