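"""End-to-end orchestration: simulate, analyze, classify, summarize, test.

``run_full_pipeline`` chains the stages on a synthetic cohort and writes a
manifest of output-file hashes so that determinism (same config + seed ->
byte-identical outputs) is checkable.  ``reproduce_printed_statistics``
recomputes every responder chi-squared statistic of the shipped count
tables from its raw counts alone -- no synthetic data involved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from pruricode import io as pio
from pruricode import marking
from pruricode.classification import classify_cohort, class_counts, mechanical_profile_for_threshold
from pruricode.config import AnalysisConfig
from pruricode.psychophysics import ContingencyTable2x2, responder_table, summarize_series
from pruricode.stats import fisher_exact_2x2, format_statistic, pearson_chi2_2x2
from pruricode.synth import CohortConfig, CohortDataset, generate_cohort

log = logging.getLogger("pruricode.pipeline")

PACKAGED_COUNTS = "printed_counts.json"


def load_printed_counts(path: Optional[str | Path] = None) -> dict:
    """Load the shipped (or an external) printed-count fixture."""
    if path is None:
        with resources.files("pruricode.data").joinpath(PACKAGED_COUNTS).open() as fh:
            return json.load(fh)
    return json.loads(Path(path).read_text())


def reproduce_printed_statistics(counts: Optional[dict | str | Path] = None) -> pd.DataFrame:
    """Recompute every chi-squared statistic from its 2x2 counts.

    Returns one row per table: recomputed statistic (2 dp), the reported
    statistic, and a match flag.
    """
    if counts is None or isinstance(counts, (str, Path)):
        counts = load_printed_counts(counts)
    rows = []
    for entry in counts["chi2_tables"]:
        table = ContingencyTable2x2(
            a=entry["a"], b=entry["b"], c=entry["c"], d=entry["d"], label=entry["label"]
        )
        result = pearson_chi2_2x2(table)
        recomputed = format_statistic(result.statistic)
        # agreement to the printed precision: within one unit in the last
        # printed digit (tolerates rounded vs truncated reporting)
        match = abs(result.statistic - entry["reported_chi2"]) < 0.01
        rows.append(
            {
                "label": entry["label"],
                "a": entry["a"], "b": entry["b"], "c": entry["c"], "d": entry["d"],
                "chi2_recomputed": recomputed,
                "chi2_reported": entry["reported_chi2"],
                "p_recomputed": format_statistic(result.p_value, 4),
                "match": match,
            }
        )
    for entry in counts.get("fisher_tables", []):
        table = ContingencyTable2x2(
            a=entry["a"], b=entry["b"], c=entry["c"], d=entry["d"], label=entry["label"]
        )
        result = fisher_exact_2x2(table)
        rows.append(
            {
                "label": entry["label"],
                "a": entry["a"], "b": entry["b"], "c": entry["c"], "d": entry["d"],
                "chi2_recomputed": None,
                "chi2_reported": None,
                "p_recomputed": format_statistic(result.p_value, 4),
                "match": None,
            }
        )
    return pd.DataFrame(rows)


def analyze_traces(dataset: CohortDataset, config: AnalysisConfig) -> pd.DataFrame:
    """Marking analysis of every chemically stimulated trace in a cohort."""
    records = []
    for trace, truth, label, substance in dataset.traces:
        periods = marking.detect_activation_periods(
            trace, config.marking, window_s=config.analysis_window_s
        )
        summary = marking.summarize_chemical_response(
            periods, config.activation_criterion_ms, fiber_id=trace.fiber_id
        )
        bursting = marking.detect_slow_bursting(
            trace, periods, config.bursting, policy=config.marking
        )
        records.append(
            {
                "fiber_id": trace.fiber_id,
                "class_label": label,
                "substance": substance,
                "n_activation_periods": summary.n_activation_periods,
                "cumulative_latency_ms": summary.cumulative_latency_ms,
                "activated": summary.activated,
                "bursting": bursting.is_bursting,
                "true_activated": truth.is_activated,
                "true_bursting": truth.is_bursting,
            }
        )
    return pd.DataFrame(records)


@dataclass
class PipelineRun:
    out_dir: Path
    seed: int
    manifest: dict[str, str]

    def manifest_hash(self) -> str:
        blob = json.dumps(self.manifest, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(
    out_dir: str | Path,
    seed: int,
    cohort_config: Optional[CohortConfig] = None,
    analysis_config: Optional[AnalysisConfig] = None,
) -> PipelineRun:
    """Simulate a cohort, analyze it end to end, and write all outputs.

    Stages: simulate -> analyze-traces -> classify -> psychophysics ->
    statistics -> reproduction report.  Any stage failure aborts with the
    stage name attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or CohortConfig()
    analysis_config = analysis_config or AnalysisConfig()

    outputs: dict[str, Path] = {}
    stage = "simulate"
    try:
        log.info("stage=%s seed=%d config=%s", stage, seed, asdict(cohort_config))
        dataset = generate_cohort(cohort_config, seed)
        pio.write_rating_series(dataset.ratings, out_dir / "ratings.csv")
        outputs["ratings.csv"] = out_dir / "ratings.csv"

        stage = "analyze-traces"
        responses = analyze_traces(dataset, analysis_config)
        responses.to_csv(out_dir / "response_summaries.csv", index=False)
        outputs["response_summaries.csv"] = out_dir / "response_summaries.csv"
        table = marking.activation_table(responses.to_dict("records"))
        table.to_csv(out_dir / "activation_table.csv", index=False)
        outputs["activation_table.csv"] = out_dir / "activation_table.csv"

        stage = "classify"
        runs = [
            (trace, mechanical_profile_for_threshold(thr))
            for trace, _, thr in dataset.classification_runs
        ]
        classification = classify_cohort(runs, analysis_config.classification)
        classification.to_csv(out_dir / "classification.csv", index=False)
        outputs["classification.csv"] = out_dir / "classification.csv"

        stage = "psychophysics"
        summaries = [
            summarize_series(
                s,
                analysis_config.psychophysics.responder_threshold,
                analysis_config.psychophysics.auc_method,
            )
            for s in dataset.ratings
        ]
        sm_frame = pd.DataFrame([asdict(s) for s in summaries])
        sm_frame.to_csv(out_dir / "summaries.csv", index=False)
        outputs["summaries.csv"] = out_dir / "summaries.csv"

        stage = "statistics"
        tests = []
        tables_json = []
        for substance in sorted({s.substance for s in summaries}):
            inj = [s for s in summaries if s.substance == substance and s.application_mode == "injection"]
            foc = [s for s in summaries if s.substance == substance and s.application_mode == "focal"]
            if not inj or not foc:
                continue
            for outcome in ("itch", "pain"):
                label = f"{substance}_{outcome}_injection_vs_focal"
                tab = responder_table(inj, foc, outcome, label=label)
                result = pearson_chi2_2x2(tab)
                tables_json.append({"label": label, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d})
                tests.append(
                    {
                        "test_name": result.test_name,
                        "label": label,
                        "statistic": format_statistic(result.statistic),
                        "df": result.df,
                        "p_value": format_statistic(result.p_value, 4),
                    }
                )
        (out_dir / "responder_tables.json").write_text(json.dumps(tables_json, indent=2))
        outputs["responder_tables.json"] = out_dir / "responder_tables.json"
        pd.DataFrame(tests).to_csv(out_dir / "tests.csv", index=False)
        outputs["tests.csv"] = out_dir / "tests.csv"

        stage = "reproduce"
        report = reproduce_printed_statistics()
        report.to_csv(out_dir / "reproduction_report.csv", index=False)
        outputs["reproduction_report.csv"] = out_dir / "reproduction_report.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {name: _sha256(path) for name, path in sorted(outputs.items())}
    manifest_payload = {
        "seed": seed,
        "analysis_config": analysis_config.model_dump(),
        "files": manifest,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest_payload, indent=2, sort_keys=True))
    return PipelineRun(out_dir=out_dir, seed=seed, manifest=manifest)
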