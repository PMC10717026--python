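"""Analysis configuration: every threshold of the pipeline in one place.

Defaults encode the study constants: the 5 ms cumulative-latency activation
criterion, the slow-bursting pattern definition (<= 4 s discharge train,
>= 20 s / five tracked stimuli of silence, >= 3 repetitions), the CM/CMi/VHT
classification thresholds (ADS 5%, recovery 24% within 40 s, von Frey
10 g / 22 g) and the NRS responder threshold of 1.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator


class MarkingThresholdPolicy(BaseModel):
    """Threshold for calling a latency step a 'sudden increase' (marking).

    A period is detected when the latency difference to the previous
    stimulus exceeds ``max(absolute_floor_ms, jitter_multiplier * sigma)``,
    with sigma estimated from the last ``baseline_window`` pre-application
    latencies.
    """

    absolute_floor_ms: float = Field(0.5, gt=0)
    jitter_multiplier: float = Field(3.0, gt=0)
    baseline_window: int = Field(20, gt=0)


class BurstingParams(BaseModel):
    burst_window_s: float = Field(4.0, gt=0)
    min_silence_s: float = Field(20.0, gt=0)
    n_silent_stimuli: int = Field(5, gt=0)
    min_repetitions: int = Field(3, gt=0)


class ClassificationParams(BaseModel):
    ads_percent: float = Field(5.0, gt=0)
    recovery_percent: float = Field(24.0, gt=0)
    recovery_window_s: float = Field(40.0, gt=0)
    vht_force_g: float = Field(10.0, gt=0)
    cm_max_force_g: float = Field(22.0, gt=0)
    initial_latency_pulses: int = Field(3, gt=0)


class PsychophysicsParams(BaseModel):
    grid_s: float = Field(10.0, gt=0)
    responder_threshold: float = Field(1.0, gt=0)
    relevant_reduction_auc: float = Field(5.0, gt=0)
    erythema_widespread_cm2: float = Field(1.0, gt=0)
    auc_method: Literal["sum", "trapezoid"] = "sum"


class AnalysisConfig(BaseModel):
    """Complete configuration for the trace/psychophysics analysis stages."""

    marking: MarkingThresholdPolicy = Field(default_factory=MarkingThresholdPolicy)
    bursting: BurstingParams = Field(default_factory=BurstingParams)
    activation_criterion_ms: float = Field(5.0, gt=0)
    analysis_window_s: float = Field(300.0, gt=0)
    classification: ClassificationParams = Field(default_factory=ClassificationParams)
    psychophysics: PsychophysicsParams = Field(default_factory=PsychophysicsParams)
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _silence_consistency(self) -> "AnalysisConfig":
        # at 0.25 Hz tracking, n_silent_stimuli stimuli span
        # (n_silent_stimuli) * 4 s >= min_silence_s must hold for the two
        # silence definitions to agree
        if self.bursting.n_silent_stimuli * 4.0 < self.bursting.min_silence_s:
            raise ValueError(
                "n_silent_stimuli x 4 s at 0.25 Hz tracking is shorter than "
                "min_silence_s; the silence criteria would disagree"
            )
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))
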